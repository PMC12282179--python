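"""Spacer-to-genome and spacer-to-spacer matching.

The matching contract is exhaustive: every placement of a spacer on
either strand of a reference with identity at or above the threshold
(80% by default) is reported.  Identity is the number of matching
positions divided by the *spacer length* — a deliberately conservative
denominator.  The default mode is ungapped sliding comparison,
vectorised over all offsets; an optional gapped mode aligns the spacer
end-to-end against local windows allowing up to two indels.

Self-hits — placements falling inside the query spacer's own source
array — are removed, mirroring the mandatory cleanup when spacers are
matched back against the very genomes they came from.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict

import edlib
import numpy as np
import pandas as pd

from .seqs import canonical, encode, revcomp


@dataclasses.dataclass
class Spacer:
    """A query spacer with optional provenance for self-hit removal."""

    spacer_id: str
    seq: str
    strain_id: str = ""
    contig_id: str = ""  # contig of the source array
    array_start: int = -1  # source array interval, -1 when unknown
    array_end: int = -1


@dataclasses.dataclass
class SpacerMatch:
    query_id: str
    target_id: str
    start: int
    end: int
    strand: str
    identity: float  # percent of spacer length
    category: str = "unassigned"


def dedupe_spacers(spacers: list[Spacer]) -> list[Spacer]:
    """Collapse exact and reverse-complement duplicates within a genome.

    The representative keeps the first-seen id but its sequence is
    normalised to the canonical strand (lexicographic minimum of the two
    orientations), so downstream exact matching is strand-free.
    """
    seen: dict[tuple[str, str], Spacer] = {}
    for sp in spacers:
        key = (sp.strain_id, canonical(sp.seq))
        if key not in seen:
            seen[key] = dataclasses.replace(sp, seq=canonical(sp.seq))
    return list(seen.values())


def _scan_ungapped(
    spacer: np.ndarray, ref: np.ndarray, max_mismatch: int
) -> list[tuple[int, int]]:
    """All offsets with <= max_mismatch mismatches; returns (offset, mm)."""
    L = len(spacer)
    if len(ref) < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(ref, L)
    mm = (windows != spacer).sum(axis=1)
    idx = np.nonzero(mm <= max_mismatch)[0]
    return [(int(i), int(mm[i])) for i in idx]


def match_spacers_to_reference(
    spacers: list[Spacer],
    reference: dict[str, str],
    min_identity: float = 0.80,
    mode: str = "ungapped",
    max_gaps: int = 2,
    remove_self: bool = True,
) -> list[SpacerMatch]:
    """All qualifying placements of each spacer on each reference contig.

    ``min_identity`` is a fraction in (0.5, 1].  In ``ungapped`` mode a
    placement at offset *o* covers ``[o, o + len(spacer))`` and identity
    is matching positions over spacer length.  In ``gapped`` mode the
    spacer is aligned end-to-end against windows of length within
    ``max_gaps`` of the spacer length, and identity is
    ``(L - edit_distance) / L`` — a lower bound on matched positions.
    Minus-strand placements are found by scanning the reverse-complement
    spacer; reported coordinates are always on the reference's forward
    strand.
    """
    if not 0.5 < min_identity <= 1:
        raise ValueError("min_identity must be in (0.5, 1]")
    if mode not in ("ungapped", "gapped"):
        raise ValueError(f"unknown matching mode {mode!r}")
    matches: list[SpacerMatch] = []
    enc_ref = {cid: encode(seq) for cid, seq in reference.items()}
    for sp in spacers:
        L = len(sp.seq)
        max_mm = int(np.floor((1 - min_identity) * L + 1e-9))
        for cid, ref_arr in enc_ref.items():
            for strand, query in (("+", sp.seq), ("-", revcomp(sp.seq))):
                if mode == "ungapped":
                    hits = _scan_ungapped(encode(query), ref_arr, max_mm)
                    for off, mm in hits:
                        matches.append(
                            SpacerMatch(
                                query_id=sp.spacer_id,
                                target_id=cid,
                                start=off,
                                end=off + L,
                                strand=strand,
                                identity=100.0 * (L - mm) / L,
                            )
                        )
                else:
                    matches.extend(
                        _gapped_hits(sp, query, strand, cid, reference[cid], min_identity, max_gaps)
                    )
    if remove_self:
        matches = [m for m in matches if not _is_self(m, spacers)]
    else:
        for m in matches:
            if _is_self(m, spacers):
                m.category = "array_self"
    matches.sort(key=lambda m: (m.query_id, m.target_id, m.start, m.strand))
    return matches


def _gapped_hits(
    sp: Spacer,
    query: str,
    strand: str,
    cid: str,
    ref: str,
    min_identity: float,
    max_gaps: int,
) -> list[SpacerMatch]:
    L = len(query)
    k = int(np.floor((1 - min_identity) * L + 1e-9))
    res = edlib.align(query, ref, mode="HW", task="locations", k=k)
    out = []
    if res["editDistance"] < 0:
        return out
    seen: set[tuple[int, int]] = set()
    for s0, e0 in res["locations"]:
        e0 = e0 + 1  # edlib end is inclusive
        if abs((e0 - s0) - L) > max_gaps or (s0, e0) in seen:
            continue
        seen.add((s0, e0))
        d = edlib.align(query, ref[s0:e0], mode="NW", task="distance")["editDistance"]
        identity = 100.0 * (L - d) / L
        if identity >= 100.0 * min_identity - 1e-9:
            out.append(
                SpacerMatch(
                    query_id=sp.spacer_id,
                    target_id=cid,
                    start=s0,
                    end=e0,
                    strand=strand,
                    identity=identity,
                )
            )
    return out


def _is_self(m: SpacerMatch, spacers: list[Spacer]) -> bool:
    for sp in spacers:
        if sp.spacer_id == m.query_id:
            if sp.array_start < 0:
                return False
            return (
                m.target_id == sp.contig_id
                and m.start < sp.array_end
                and m.end > sp.array_start
            )
    return False


def _spacer_pair_qualifies(a: str, b: str, min_identity: float) -> bool:
    """Does spacer ``a`` place on spacer ``b`` at the identity threshold?"""
    L = len(a)
    max_mm = int(np.floor((1 - min_identity) * L + 1e-9))
    if min_identity >= 1.0:
        return canonical(a) == canonical(b) if L == len(b) else (a in b or revcomp(a) in b)
    eb = encode(b)
    for query in (a, revcomp(a)):
        if _scan_ungapped(encode(query), eb, max_mm):
            return True
    return False


@dataclasses.dataclass
class SharingSummary:
    """Cross-strain shared-spacer counts plus per-strain totals."""

    counts: pd.DataFrame  # index/columns: strain ids; [i, j] = i's spacers matching j
    totals: pd.Series  # unique spacers per strain

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        for qi in self.counts.index:
            for ti in self.counts.columns:
                if qi != ti and self.counts.loc[qi, ti] > 0:
                    rows.append((qi, ti, int(self.counts.loc[qi, ti])))
        return pd.DataFrame(rows, columns=["query", "reference", "n_matched"])


def sharing_matrix(
    per_strain: dict[str, list[Spacer]], min_identity: float = 0.80
) -> SharingSummary:
    """Pairwise shared-spacer counts between strains.

    Entry (A, B) counts A's unique spacers with at least one qualifying
    placement among B's spacers (both strands).  At ``min_identity`` 1.0
    this reduces to exact / reverse-complement equality.  The diagonal
    is left at zero.
    """
    if len(per_strain) < 2:
        raise ValueError("sharing_matrix needs at least 2 strains")
    uniq = {s: dedupe_spacers(sps) for s, sps in per_strain.items()}
    strains = sorted(uniq)
    mat = pd.DataFrame(0, index=strains, columns=strains, dtype=int)
    for qa in strains:
        for tb in strains:
            if qa == tb:
                continue
            n = 0
            for sp in uniq[qa]:
                if any(
                    _spacer_pair_qualifies(sp.seq, other.seq, min_identity)
                    for other in uniq[tb]
                ):
                    n += 1
            mat.loc[qa, tb] = n
    totals = pd.Series({s: len(uniq[s]) for s in strains})
    return SharingSummary(counts=mat, totals=totals)


def matches_to_table(matches: list[SpacerMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(m) for m in matches],
        columns=["query_id", "target_id", "start", "end", "strand", "identity", "category"],
    )


def spacers_from_truth(
    spacer_table: pd.DataFrame, array_table: pd.DataFrame
) -> list[Spacer]:
    """Build query spacers (with source-array intervals) from a truth table."""
    bounds = {
        (r.strain_id, r.contig_id, r.array_index): (r.start, r.end)
        for r in array_table.itertuples()
    }
    out = []
    for r in spacer_table.itertuples():
        a0, a1 = bounds[(r.strain_id, r.contig_id, r.array_index)]
        out.append(
            Spacer(
                spacer_id=f"{r.strain_id}|{r.contig_id}|array{r.array_index}|spacer{r.spacer_index}",
                seq=r.seq,
                strain_id=r.strain_id,
                contig_id=r.contig_id,
                array_start=a0,
                array_end=a1,
            )
        )
    return out


def spacers_from_arrays(arrays) -> list[Spacer]:
    """Query spacers from detected arrays, carrying source intervals."""
    out = []
    counter: dict[tuple[str, str], int] = defaultdict(int)
    for a in arrays:
        key = (a.strain_id, a.contig_id)
        counter[key] += 1
        n = counter[key]
        for m, seq in enumerate(a.spacers, start=1):
            out.append(
                Spacer(
                    spacer_id=f"{a.strain_id}|{a.contig_id}|array{n}|spacer{m}",
                    seq=seq,
                    strain_id=a.strain_id,
                    contig_id=a.contig_id,
                    array_start=a.start,
                    array_end=a.end,
                )
            )
    return out
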