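"""Direct-repeat typing and hairpin (tetraloop) analysis.

Repeats are assigned a CRISPR type/subtype by Levenshtein distance to a
reference catalog, strand-aware: a query is accepted when its nearest
catalog entry (over both strands) is within ``max_edits`` (default 4).
Type I-E repeats are palindromic and fold into a stem-loop; the loop —
a 4-nt "tetraloop" in the systems modelled here — is extracted by an
exact-complement hairpin search.
"""

from __future__ import annotations

import dataclasses

import edlib
import pandas as pd

from .array_detection import CrisprArray
from .seqs import revcomp, validate_dna

# Default catalog entries.  These are synthetic representative repeats
# (the same base sequences the synthetic panel generator plants), not
# sequences taken from any particular organism: an I-E-style palindrome
# (5-nt tail, 7-bp stem arms, 4-nt loop, 6-nt tail) and a II-C-style
# repeat with no strong secondary structure.
IE_TAIL5 = "TGTTA"
IE_ARM5 = "GCCGGTC"
IE_ARM3 = revcomp(IE_ARM5)
IE_TAIL3 = "ATAAAC"
DEFAULT_IE_LOOP = "GTTCG"[:4]  # "GTTC"


def build_ie_repeat(tetraloop: str) -> str:
    """Assemble the I-E-style palindromic repeat around a 4-nt tetraloop."""
    if len(tetraloop) != 4:
        raise ValueError("tetraloop must be 4 nt")
    validate_dna(tetraloop, allow_n=False)
    return IE_TAIL5 + IE_ARM5 + tetraloop + IE_ARM3 + IE_TAIL3


DEFAULT_IIC_REPEAT = "CTTTCAATTCCTTGTTGGCAAGGGATTGA"


@dataclasses.dataclass
class RepeatCatalog:
    """Reference repeats with their CRISPR type/subtype labels."""

    entries: list[tuple[str, str, str]]  # (repeat_seq, type, subtype)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("repeat catalog must be non-empty")
        seqs = [e[0] for e in self.entries]
        if len(set(seqs)) != len(seqs):
            raise ValueError("repeat catalog entries must be unique")
        for s in seqs:
            validate_dna(s, allow_n=False)

    @classmethod
    def default(cls) -> "RepeatCatalog":
        return cls(
            entries=[
                (build_ie_repeat(DEFAULT_IE_LOOP), "I", "I-E"),
                (DEFAULT_IIC_REPEAT, "II", "II-C"),
            ]
        )

    @classmethod
    def from_tsv(cls, path) -> "RepeatCatalog":
        from .io import read_repeat_catalog_tsv

        return cls(entries=read_repeat_catalog_tsv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["repeat", "type", "subtype"])


@dataclasses.dataclass
class RepeatClassification:
    query: str
    best_entry: tuple[str, str, str] | None
    edit_distance: int
    accepted: bool

    @property
    def subtype(self) -> str | None:
        return self.best_entry[2] if self.best_entry else None


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance."""
    return edlib.align(a, b, task="distance")["editDistance"]


def classify_repeat(
    query: str, catalog: RepeatCatalog, max_edits: int = 4
) -> RepeatClassification:
    """Nearest-catalog-entry typing of a direct repeat.

    The distance is the minimum Levenshtein distance over catalog
    entries and both strands of the query; ties break by catalog order.
    A repeat is accepted as a true CRISPR repeat when the distance is
    ``max_edits`` or fewer.
    """
    if len(query) < 16:
        raise ValueError("repeat query must be at least 16 nt")
    validate_dna(query, allow_n=False)
    rc = revcomp(query)
    best_entry = None
    best_d = None
    for entry in catalog.entries:
        d = min(levenshtein(query, entry[0]), levenshtein(rc, entry[0]))
        if best_d is None or d < best_d:
            best_d, best_entry = d, entry
    assert best_d is not None
    return RepeatClassification(
        query=query,
        best_entry=best_entry,
        edit_distance=best_d,
        accepted=best_d <= max_edits,
    )


def assign_types(
    arrays: list[CrisprArray], catalog: RepeatCatalog | None = None, max_edits: int = 4
) -> list[RepeatClassification]:
    """Type each array in place from its consensus repeat; returns details.

    Accepted repeats get their catalog subtype if it is I-E or II-C and
    ``other`` otherwise; rejected repeats stay ``unassigned``.
    """
    catalog = catalog or RepeatCatalog.default()
    out = []
    for a in arrays:
        cls = classify_repeat(a.consensus_repeat, catalog, max_edits=max_edits)
        if cls.accepted:
            a.system_type = cls.subtype if cls.subtype in ("I-E", "II-C") else "other"
        else:
            a.system_type = "unassigned"
        out.append(cls)
    return out


_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclasses.dataclass
class HairpinStructure:
    """An exact-complement stem-loop within a direct repeat.

    ``arm5_start`` / ``arm3_end`` are offsets within the repeat
    (half-open on the 3' side); the two arms are exact reverse
    complements of each other.
    """

    stem_len: int
    arm5_start: int
    arm3_end: int
    loop_seq: str
    tail5: str
    tail3: str


def fold_hairpin(
    repeat: str, min_stem: int = 5, min_loop: int = 3
) -> HairpinStructure | None:
    """Best exact-complement hairpin of a repeat, or None.

    Among all contiguous arm pairs (no wobble pairs, no bulges) with a
    loop of at least ``min_loop`` nt — shorter loops are sterically
    impossible — the fold maximises stem length, breaking ties by
    smaller loop, then by leftmost 5' arm.  Quadratic-time run-length
    recursion; repeats are short so cost is negligible.
    """
    validate_dna(repeat, allow_n=False)
    n = len(repeat)
    # run[i][j]: length of exact-complement run pairing i..i+t with j-t..j
    run = [[0] * (n + 2) for _ in range(n + 2)]
    for i in range(n - 1, -1, -1):
        for j in range(n - 1, i, -1):
            if (repeat[i], repeat[j]) in _PAIRS:
                inner = run[i + 1][j - 1] if j - 1 > i + 1 else 0
                run[i][j] = 1 + inner
    best: tuple[int, int, int] | None = None  # (stem, loop, arm5_start); j derived
    best_j = -1
    for i in range(n):
        for j in range(i + 1, n):
            max_s = min(run[i][j], (j - i + 1 - min_loop) // 2)
            if max_s < min_stem:
                continue
            s = max_s
            loop = j - i + 1 - 2 * s
            key = (s, -loop, -i)
            if best is None or key > (best[0], -best[1], -best[2]):
                best = (s, loop, i)
                best_j = j
    if best is None:
        return None
    s, loop, i = best
    j = best_j
    return HairpinStructure(
        stem_len=s,
        arm5_start=i,
        arm3_end=j + 1,
        loop_seq=repeat[i + s : j + 1 - s],
        tail5=repeat[:i],
        tail3=repeat[j + 1 :],
    )


def tetraloop_census(
    arrays: list[CrisprArray], min_stem: int = 5
) -> pd.DataFrame:
    """Count I-E arrays per (strain, context, tetraloop).

    Arrays whose consensus repeat does not fold to a qualifying hairpin
    are tallied under loop ``NA``.
    """
    rows = []
    for a in arrays:
        if a.system_type != "I-E":
            continue
        hp = fold_hairpin(a.consensus_repeat, min_stem=min_stem)
        loop = hp.loop_seq if hp is not None else "NA"
        rows.append((a.strain_id, a.context, loop))
    if not rows:
        return pd.DataFrame(columns=["strain_id", "context", "tetraloop", "count"])
    df = pd.DataFrame(rows, columns=["strain_id", "context", "tetraloop"])
    out = (
        df.groupby(["strain_id", "context", "tetraloop"])
        .size()
        .reset_index(name="count")
        .sort_values(["strain_id", "context", "tetraloop"])
        .reset_index(drop=True)
    )
    return out


def find_tracr_antirepeat(
    contig: str,
    repeat: str,
    operon_start: int,
    window: int = 500,
    min_len: int = 20,
) -> tuple[int, int] | None:
    """Optional II-C annotation: a tracrRNA-like anti-repeat.

    Searches the ``window`` bp upstream of the Cas operon for a reverse
    complement of at least ``min_len`` contiguous bases of the repeat.
    Returns the (start, end) of the longest such match, leftmost on
    ties, or None.
    """
    lo = max(0, operon_start - window)
    region = contig[lo:operon_start]
    best: tuple[int, int] | None = None
    for length in range(len(repeat), min_len - 1, -1):
        for off in range(0, len(repeat) - length + 1):
            probe = revcomp(repeat[off : off + length])
            idx = region.find(probe)
            if idx >= 0:
                cand = (lo + idx, lo + idx + length)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            return best
    return None
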