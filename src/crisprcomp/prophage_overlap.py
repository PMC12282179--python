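"""Attribution of spacer matches to prophage, genic and intergenic space.

Matches are first padded by 32 bp on each side (buffering imprecise
boundaries and strand uncertainty), then counted against prophage
regions: a padded match counts toward *every* region it overlaps by at
least one base, with ``questionable`` and ``incomplete`` regions pooled
into one class.  Matches touching no prophage are next checked against
CRISPR array intervals (dropped as self-hits) and finally against gene
features (genic vs intergenic).  Edge tables — one per completeness
class — summarise match counts and mean identity per (spacer source,
target strain) pair, the tab-delimited form consumed by network
viewers.

Identity is always the unpadded match's identity; padding affects
attribution only.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .spacer_matching import SpacerMatch


@dataclasses.dataclass
class ProphageRegion:
    strain_id: str
    contig_id: str
    start: int
    end: int
    completeness: str  # {intact, questionable, incomplete}
    region_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty prophage interval")
        if self.completeness not in ("intact", "questionable", "incomplete"):
            raise ValueError(f"unknown completeness {self.completeness!r}")

    @property
    def completeness_class(self) -> str:
        return "intact" if self.completeness == "intact" else "incomplete_or_questionable"


def regions_from_bed(bed: pd.DataFrame, contig_to_strain: dict[str, str]) -> list[ProphageRegion]:
    out = []
    for r in bed.itertuples():
        out.append(
            ProphageRegion(
                strain_id=contig_to_strain.get(r.contig_id, ""),
                contig_id=r.contig_id,
                start=int(r.start),
                end=int(r.end),
                completeness=r.completeness,
                region_id=str(r.region_id),
            )
        )
    return out


def pad_interval(
    start: int, end: int, pad: int, contig_len: int | None = None
) -> tuple[int, int]:
    """Extend an interval by ``pad`` on both sides, clipped at bounds."""
    s = max(0, start - pad)
    e = end + pad
    if contig_len is not None:
        e = min(e, contig_len)
    return s, e


def pad_matches(
    matches: list[SpacerMatch],
    pad: int = 32,
    contig_lengths: dict[str, int] | None = None,
) -> list[tuple[SpacerMatch, int, int]]:
    """Pair each match with its padded interval."""
    out = []
    for m in matches:
        clen = contig_lengths.get(m.target_id) if contig_lengths else None
        out.append((m, *pad_interval(m.start, m.end, pad, clen)))
    return out


@dataclasses.dataclass
class AttributionResult:
    """Partition of matches plus per-region and per-pair tallies."""

    prophage: list[tuple[SpacerMatch, ProphageRegion]]  # one entry per overlapped region
    self_dropped: list[SpacerMatch]
    genic: list[SpacerMatch]
    intergenic: list[SpacerMatch]
    region_counts: pd.DataFrame  # region_id, completeness, n_matches


def _build_trees(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for contig_id, start, end, payload in intervals:
        trees.setdefault(contig_id, IntervalTree())[start:end] = payload
    return trees


def attribute_matches(
    matches: list[SpacerMatch],
    regions: list[ProphageRegion],
    array_intervals: list[tuple[str, int, int]],
    gene_intervals: list[tuple[str, int, int]],
    pad: int = 32,
    contig_lengths: dict[str, int] | None = None,
) -> AttributionResult:
    """Classify every genome match into the four-way partition.

    ``array_intervals`` / ``gene_intervals`` are ``(contig_id, start,
    end)`` triples.

    Order matters and matches the subtract-then-intersect procedure:
    prophage counting (on padded intervals) happens first; only
    prophage-free matches are screened against arrays (self) and genes.
    A padded match overlapping several regions counts once per region
    but appears once in the partition.
    """
    region_trees = _build_trees(
        (r.contig_id, r.start, r.end, r) for r in regions
    )
    array_trees = _build_trees((c, s, e, None) for c, s, e in array_intervals)
    gene_trees = _build_trees((c, s, e, None) for c, s, e in gene_intervals)

    prophage_hits: list[tuple[SpacerMatch, ProphageRegion]] = []
    self_dropped: list[SpacerMatch] = []
    genic: list[SpacerMatch] = []
    intergenic: list[SpacerMatch] = []

    for m, ps, pe in pad_matches(matches, pad, contig_lengths):
        tree = region_trees.get(m.target_id)
        overlapped = sorted(tree[ps:pe], key=lambda iv: iv.begin) if tree else []
        if overlapped:
            for iv in overlapped:
                prophage_hits.append((m, iv.data))
            first = overlapped[0].data
            m.category = (
                "prophage_intact"
                if first.completeness_class == "intact"
                else "prophage_incomplete"
            )
            continue
        atree = array_trees.get(m.target_id)
        if atree and atree[m.start : m.end]:
            m.category = "array_self"
            self_dropped.append(m)
            continue
        gtree = gene_trees.get(m.target_id)
        if gtree and gtree[m.start : m.end]:
            m.category = "genic"
            genic.append(m)
        else:
            m.category = "intergenic"
            intergenic.append(m)

    rows = [
        {"region_id": r.region_id, "completeness": r.completeness, "strain_id": r.strain_id}
        for _, r in prophage_hits
    ]
    if rows:
        region_counts = (
            pd.DataFrame(rows)
            .groupby(["region_id", "completeness", "strain_id"])
            .size()
            .reset_index(name="n_matches")
            .sort_values("region_id")
            .reset_index(drop=True)
        )
    else:
        region_counts = pd.DataFrame(
            columns=["region_id", "completeness", "strain_id", "n_matches"]
        )
    return AttributionResult(
        prophage=prophage_hits,
        self_dropped=self_dropped,
        genic=genic,
        intergenic=intergenic,
        region_counts=region_counts,
    )


def genic_summary(result: AttributionResult) -> dict[str, int]:
    """Unique-spacer and total-match tallies for non-phage placements."""
    return {
        "genic_total": len(result.genic),
        "genic_unique": len({m.query_id for m in result.genic}),
        "intergenic_total": len(result.intergenic),
        "intergenic_unique": len({m.query_id for m in result.intergenic}),
        "nonphage_total": len(result.genic) + len(result.intergenic),
        "nonphage_unique": len(
            {m.query_id for m in result.genic} | {m.query_id for m in result.intergenic}
        ),
    }


EDGE_COLUMNS = ["source_id", "target_id", "completeness_class", "n_matches", "mean_identity"]


def edge_table(
    result: AttributionResult, source_of: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per (source, target strain, completeness class) counts and mean identity."""

    def src(qid: str) -> str:
        if source_of and qid in source_of:
            return source_of[qid]
        return qid.split("|", 1)[0]

    rows = [
        {
            "source_id": src(m.query_id),
            "target_id": r.strain_id,
            "completeness_class": r.completeness_class,
            "identity": m.identity,
        }
        for m, r in result.prophage
    ]
    if not rows:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["source_id", "target_id", "completeness_class"])
        .agg(n_matches=("identity", "size"), mean_identity=("identity", "mean"))
        .reset_index()
        .sort_values(["source_id", "target_id", "completeness_class"])
        .reset_index(drop=True)
    )
    return out[EDGE_COLUMNS]


def export_edges(
    edges: pd.DataFrame, outdir: str | Path, prefix: str = "edges"
) -> tuple[Path, Path]:
    """Write the two completeness-class edge tables, deterministic order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cls, tag in (
        ("intact", "intact"),
        ("incomplete_or_questionable", "incomplete_questionable"),
    ):
        sub = edges[edges["completeness_class"] == cls] if len(edges) else edges
        sub = sub.sort_values(["source_id", "target_id"]) if len(sub) else sub
        path = outdir / f"{prefix}.{tag}.tsv"
        (sub if len(sub) else pd.DataFrame(columns=EDGE_COLUMNS)).to_csv(
            path, sep="\t", index=False
        )
        paths.append(path)
    return tuple(paths)
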