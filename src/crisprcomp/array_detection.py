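"""CRT-style CRISPR array detection in assembled contigs.

The detector follows the classic repeat-spacer structure-finding recipe:
exact k-mer recurrences at spacer-compatible distances seed candidate
arrays, seeds are extended to full repeat boundaries by maximising
per-column agreement across the repeat copies, and two quality filters
reject the repetitive-DNA failure modes (tandem repeats whose "spacers"
are near-identical, and degenerate repeat sets).

Coordinates are 0-based half-open throughout.  For every reported array
the ordered repeats and spacers re-concatenate exactly to the contig
substring ``[start, end)`` — this reconstruction invariant is asserted
at construction time.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict

import edlib

from .io import read_fasta
from .seqs import validate_dna

#: agreement fraction required to extend a repeat boundary by one column
BOUNDARY_AGREEMENT = 0.75

#: reject arrays whose spacers average more than this pairwise identity
TANDEM_SPACER_IDENTITY = 0.60


@dataclasses.dataclass
class DetectionParams:
    """Knobs of the repeat-spacer finder (CRT-like defaults)."""

    seed_k: int = 23
    min_repeat_len: int = 19
    max_repeat_len: int = 38
    min_spacer_len: int = 19
    max_spacer_len: int = 48
    min_repeats: int = 3
    max_repeat_edits: int = 3

    def __post_init__(self) -> None:
        if self.min_repeat_len > self.max_repeat_len:
            raise ValueError("min_repeat_len > max_repeat_len")
        if self.min_spacer_len > self.max_spacer_len:
            raise ValueError("min_spacer_len > max_spacer_len")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")
        if self.seed_k > self.max_repeat_len:
            raise ValueError("seed_k must not exceed max_repeat_len")


@dataclasses.dataclass
class CrisprArray:
    """An ordered run of direct repeats and spacers on one contig."""

    strain_id: str
    contig_id: str
    start: int
    end: int
    repeats: list[str]
    spacers: list[str]
    consensus_repeat: str
    system_type: str = "unassigned"  # {I-E, II-C, other, unassigned}
    context: str = "unplaced"  # {canonical, orphan, unplaced}

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    def check_reconstruction(self, contig: str) -> None:
        parts = []
        for i, rep in enumerate(self.repeats):
            parts.append(rep)
            if i < len(self.spacers):
                parts.append(self.spacers[i])
        if "".join(parts) != contig[self.start : self.end]:
            raise AssertionError(
                f"array at {self.start}:{self.end} does not reconstruct its contig substring"
            )


def _levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def consensus_repeat(repeats: list[str]) -> str:
    """Per-column majority consensus of aligned repeat copies.

    Copies are aligned flush left.  The consensus length is the median
    copy length; per column, ties between equally frequent bases break
    to the lexicographically smaller base.
    """
    if not repeats:
        raise ValueError("consensus_repeat requires a non-empty repeat list")
    lengths = sorted(len(r) for r in repeats)
    length = lengths[(len(lengths) - 1) // 2]
    out = []
    for col in range(length):
        counts: dict[str, int] = defaultdict(int)
        for rep in repeats:
            if col < len(rep):
                counts[rep[col]] += 1
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0][0])))
        out.append(best[0])
    return "".join(out)


def _column_agrees(bases: list[str], threshold: float = BOUNDARY_AGREEMENT) -> bool:
    """True when the modal ACGT base covers >= threshold of the copies."""
    counts: dict[str, int] = defaultdict(int)
    for b in bases:
        if b in "ACGT":
            counts[b] += 1
    if not counts:
        return False
    return max(counts.values()) >= threshold * len(bases)


def _mean_pairwise_spacer_identity(spacers: list[str]) -> float:
    if len(spacers) < 2:
        return 0.0
    total = 0.0
    n = 0
    for i in range(len(spacers)):
        for j in range(i + 1, len(spacers)):
            d = _levenshtein(spacers[i], spacers[j])
            total += 1.0 - d / max(len(spacers[i]), len(spacers[j]))
            n += 1
    return total / n


class _Candidate:
    """Working state: repeat-unit start positions plus current unit length."""

    def __init__(self, contig: str, starts: list[int], length: int):
        self.contig = contig
        self.starts = starts
        self.length = length

    def repeats(self) -> list[str]:
        return [self.contig[p : p + self.length] for p in self.starts]

    def spacers(self) -> list[str]:
        return [
            self.contig[self.starts[i] + self.length : self.starts[i + 1]]
            for i in range(len(self.starts) - 1)
        ]

    def min_gap(self) -> int:
        return min(
            self.starts[i + 1] - (self.starts[i] + self.length)
            for i in range(len(self.starts) - 1)
        )


def _extend_boundaries(cand: _Candidate, params: DetectionParams) -> None:
    """Grow the repeat unit left then right while copies keep agreeing.

    Extension stops at the contig edge, at the repeat-length cap, when a
    spacer would shrink below ``min_spacer_len``, or when fewer than
    ``BOUNDARY_AGREEMENT`` of the copies agree on the next column.  The
    left-then-right order is immaterial for agreement itself (columns
    are judged independently); it only matters if the length cap binds.
    """
    contig, starts = cand.contig, cand.starts
    # left
    while True:
        if cand.length + 1 > params.max_repeat_len:
            break
        if starts[0] - 1 < 0:
            break
        if len(starts) > 1 and cand.min_gap() - 1 < params.min_spacer_len:
            break
        col = [contig[p - 1] for p in starts]
        if not _column_agrees(col):
            break
        cand.starts = starts = [p - 1 for p in starts]
        cand.length += 1
    # right
    while True:
        if cand.length + 1 > params.max_repeat_len:
            break
        if starts[-1] + cand.length >= len(contig):
            break
        if len(starts) > 1 and cand.min_gap() - 1 < params.min_spacer_len:
            break
        col = [contig[p + cand.length] for p in starts]
        if not _column_agrees(col):
            break
        cand.length += 1


def _refine_boundaries(cand: _Candidate, params: DetectionParams) -> None:
    """Re-judge boundary columns over the full unit set.

    A seed may anchor on a coincidental flank base shared by a few
    units; once all units are gathered, edge columns that fall below the
    agreement level over the whole set are trimmed back and extension is
    re-attempted, so boundaries reflect every copy.
    """
    contig = cand.contig
    for _ in range(100):
        changed = False
        while cand.length > params.min_repeat_len:
            col = [contig[p] for p in cand.starts]
            if _column_agrees(col):
                break
            cand.starts = [p + 1 for p in cand.starts]
            cand.length -= 1
            changed = True
        while cand.length > params.min_repeat_len:
            col = [contig[p + cand.length - 1] for p in cand.starts]
            if _column_agrees(col):
                break
            cand.length -= 1
            changed = True
        before = (cand.starts[0], cand.length)
        _extend_boundaries(cand, params)
        if not changed and (cand.starts[0], cand.length) == before:
            return


def _realign_units(cand: _Candidate, params: DetectionParams, radius: int = 4) -> None:
    """Shift each repeat copy to its locally best consensus alignment.

    Subset seeding can leave individual copies offset by a base or two;
    each copy is slid within ``radius`` bp to minimise edit distance to
    the consensus (ties to the smallest shift, then leftmost).  Moves
    that would break the left-to-right unit order are skipped.
    """
    del params
    contig = cand.contig
    cons = consensus_repeat(cand.repeats())
    new_starts: list[int] = []
    for idx, p in enumerate(cand.starts):
        best = (len(cons) + 1, 0)  # (distance, shift)
        for d in range(-radius, radius + 1):
            s = p + d
            window = contig[s : s + cand.length]
            if s < 0 or len(window) < cand.length or "N" in window:
                continue
            dist = _levenshtein(cons, window)
            if (dist, abs(d), d) < (best[0], abs(best[1]), best[1]):
                best = (dist, d)
        s = p + best[1]
        if new_starts and s <= new_starts[-1]:
            s = p
        new_starts.append(s)
    cand.starts = new_starts


def _grow_maximal(cand: _Candidate, params: DetectionParams) -> None:
    """Append repeat units beyond either end while a qualifying copy exists.

    A qualifying copy matches the current consensus within
    ``max_repeat_edits`` at a spacer-compatible distance.  Among
    candidate placements the one with the fewest edits wins, leftmost on
    ties.
    """
    contig = cand.contig

    def best_copy(lo: int, hi: int) -> int | None:
        cons = consensus_repeat(cand.repeats())
        best: tuple[int, int] | None = None
        for s in range(max(lo, 0), hi + 1):
            window = contig[s : s + cand.length]
            if len(window) < cand.length or "N" in window:
                continue
            d = _levenshtein(cons, window)
            if d <= params.max_repeat_edits and (best is None or d < best[0]):
                best = (d, s)
        return None if best is None else best[1]

    while True:
        first = cand.starts[0]
        s = best_copy(
            first - params.max_spacer_len - cand.length,
            first - params.min_spacer_len - cand.length,
        )
        if s is None:
            break
        cand.starts.insert(0, s)
    while True:
        last = cand.starts[-1]
        s = best_copy(
            last + cand.length + params.min_spacer_len,
            last + cand.length + params.max_spacer_len,
        )
        if s is None:
            break
        cand.starts.append(s)


def detect_arrays(
    contig: str,
    params: DetectionParams | None = None,
    strain_id: str = "",
    contig_id: str = "",
) -> list[CrisprArray]:
    """Find CRISPR arrays on one contig.

    Seeds are exact ``seed_k``-mer recurrences at distances compatible
    with one repeat plus one spacer; the leftmost qualifying seed claims
    each array (leftmost-maximal placement).  Returned arrays are sorted
    by start and satisfy the reconstruction invariant.
    """
    params = params or DetectionParams()
    contig = contig.upper()
    validate_dna(contig, allow_n=True)
    k = params.seed_k
    gap_lo = params.min_repeat_len + params.min_spacer_len
    gap_hi = params.max_repeat_len + params.max_spacer_len

    kmer_pos: dict[str, list[int]] = defaultdict(list)
    for i in range(len(contig) - k + 1):
        kmer = contig[i : i + k]
        if "N" not in kmer:
            kmer_pos[kmer].append(i)

    arrays: list[CrisprArray] = []
    claimed_until = -1
    i = 0
    while i <= len(contig) - k:
        if i <= claimed_until:
            i = claimed_until + 1
            continue
        positions = kmer_pos.get(contig[i : i + k], ())
        if len(positions) < 2 or positions[0] != i:
            i += 1
            continue
        # greedy chain of seed recurrences at spacer-compatible distances
        chain = [i]
        for p in positions:
            if gap_lo <= p - chain[-1] <= gap_hi:
                chain.append(p)
        if len(chain) < params.min_repeats:
            i += 1
            continue

        cand = _Candidate(contig, chain, k)
        _extend_boundaries(cand, params)
        _grow_maximal(cand, params)
        for _ in range(2):
            _realign_units(cand, params)
            _refine_boundaries(cand, params)

        array = _finalize(cand, params, strain_id, contig_id)
        if array is None:
            i += 1
            continue
        arrays.append(array)
        claimed_until = array.end - 1
        i = claimed_until + 1

    arrays.sort(key=lambda a: a.start)
    return arrays


def _finalize(
    cand: _Candidate, params: DetectionParams, strain_id: str, contig_id: str
) -> CrisprArray | None:
    repeats = cand.repeats()
    spacers = cand.spacers()
    if len(repeats) < params.min_repeats:
        return None
    if not (params.min_repeat_len <= cand.length <= params.max_repeat_len):
        return None
    if any("N" in r for r in repeats):
        return None
    if any(
        not (params.min_spacer_len <= len(s) <= params.max_spacer_len) for s in spacers
    ):
        return None
    cons = consensus_repeat(repeats)
    # repeat-degeneracy guard
    if any(_levenshtein(r, cons) > params.max_repeat_edits for r in repeats):
        return None
    # tandem-repeat guard
    if _mean_pairwise_spacer_identity(spacers) > TANDEM_SPACER_IDENTITY:
        return None
    array = CrisprArray(
        strain_id=strain_id,
        contig_id=contig_id,
        start=cand.starts[0],
        end=cand.starts[-1] + cand.length,
        repeats=repeats,
        spacers=spacers,
        consensus_repeat=cons,
    )
    array.check_reconstruction(cand.contig)
    return array


def strain_scan(
    assembly: dict[str, str] | str,
    params: DetectionParams | None = None,
    strain_id: str = "",
) -> list[CrisprArray]:
    """Run :func:`detect_arrays` over every contig of an assembly.

    ``assembly`` may be a FASTA path or an ``{contig_id: seq}`` mapping
    (duplicate ids rejected at the FASTA boundary).
    """
    if isinstance(assembly, (str,)):
        assembly = read_fasta(assembly)
    arrays: list[CrisprArray] = []
    for contig_id, seq in assembly.items():
        arrays.extend(
            detect_arrays(seq, params, strain_id=strain_id, contig_id=contig_id)
        )
    return arrays


def arrays_to_table(arrays: list[CrisprArray]):
    """Summarise arrays as the bulk-collection TSV (one row per array)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "strain_id": a.strain_id,
                "contig_id": a.contig_id,
                "start": a.start,
                "end": a.end,
                "n_repeats": len(a.repeats),
                "n_spacers": a.n_spacers,
                "consensus_repeat": a.consensus_repeat,
                "system_type": a.system_type,
                "context": a.context,
            }
            for a in arrays
        ],
        columns=[
            "strain_id",
            "contig_id",
            "start",
            "end",
            "n_repeats",
            "n_spacers",
            "consensus_repeat",
            "system_type",
            "context",
        ],
    )


def spacer_fasta_records(arrays: list[CrisprArray]) -> list[tuple[str, str]]:
    """Systematic spacer ids: ``strain|contig|arrayN|spacerM``."""
    records = []
    counter: dict[tuple[str, str], int] = defaultdict(int)
    for a in arrays:
        key = (a.strain_id, a.contig_id)
        counter[key] += 1
        n = counter[key]
        for m, sp in enumerate(a.spacers, start=1):
            records.append((f"{a.strain_id}|{a.contig_id}|array{n}|spacer{m}", sp))
    return records
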