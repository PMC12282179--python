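"""Canonical vs orphan labelling of arrays by proximity to Cas genes.

An array is *canonical* when the gap to the nearest annotated Cas gene
on the same contig is at most ``max_dist`` (500 bp by default), and
*orphan* when the gap is larger or no Cas gene shares the contig.  The
gap is the bedtools-closest convention: the number of bases strictly
between the two intervals, 0 for any overlap or abutment.
"""

from __future__ import annotations

import dataclasses
import re

from .array_detection import CrisprArray
from .io import read_gff

#: gene names treated as Cas genes when reading annotations
DEFAULT_CAS_PATTERN = r"^(cas\d*|cse\d|csy\d|csn\d|cas\d+[a-z])$"


@dataclasses.dataclass
class CasGene:
    contig_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty cas gene interval {self.start}:{self.end}")


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Bases strictly between two half-open intervals; 0 if they touch."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def nearest_feature(
    interval: tuple[int, int], features: list
) -> tuple[object | None, int | None]:
    """Minimal-gap feature for an interval; leftmost feature start on ties.

    Features need ``start``/``end`` attributes.  Returns ``(None, None)``
    for an empty feature list.
    """
    if not features:
        return None, None
    start, end = interval
    best = min(
        features, key=lambda f: (interval_gap(start, end, f.start, f.end), f.start)
    )
    return best, interval_gap(start, end, best.start, best.end)


def classify_context(
    array: CrisprArray, cas_genes: list[CasGene], max_dist: int = 500
) -> str:
    """Label one array ``canonical`` or ``orphan`` (gap strictly over
    ``max_dist``, or no Cas gene on the contig, means orphan)."""
    same_contig = [g for g in cas_genes if g.contig_id == array.contig_id]
    _, gap = nearest_feature((array.start, array.end), same_contig)
    if gap is None or gap > max_dist:
        return "orphan"
    return "canonical"


def classify_contexts(
    arrays: list[CrisprArray], cas_genes: list[CasGene], max_dist: int = 500
) -> None:
    """Label every array in place."""
    for a in arrays:
        a.context = classify_context(a, cas_genes, max_dist=max_dist)


def read_cas_genes(
    gff_path, pattern: str = DEFAULT_CAS_PATTERN
) -> list[CasGene]:
    """Pull Cas genes from a GFF3 file by gene-name regex (case-insensitive)."""
    rx = re.compile(pattern, re.IGNORECASE)
    genes = []
    for f in read_gff(gff_path, ftype="gene"):
        if rx.match(f.name):
            genes.append(
                CasGene(
                    contig_id=f.contig_id,
                    start=f.start,
                    end=f.end,
                    strand=f.strand,
                    name=f.name,
                )
            )
    return genes
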