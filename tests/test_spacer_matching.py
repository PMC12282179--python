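"""Matching contracts: dedup, identity thresholding, self-hits, sharing."""

import numpy as np
import pytest

from crisprcomp.seqs import canonical, random_dna, revcomp
from crisprcomp.spacer_matching import (
    Spacer,
    dedupe_spacers,
    match_spacers_to_reference,
    sharing_matrix,
)


def brute_force_matches(spacer: str, ref: str, min_identity: float):
    """All-offsets, both-strands ungapped scan (oracle); returns (start, strand)."""
    L = len(spacer)
    out = set()
    max_mm = int(np.floor((1 - min_identity) * L + 1e-9))
    for strand, q in (("+", spacer), ("-", revcomp(spacer))):
        for off in range(len(ref) - L + 1):
            mm = 0
            for a, b in zip(q, ref[off : off + L]):
                if a != b:
                    mm += 1
                    if mm > max_mm:
                        break
            if mm <= max_mm:
                out.add((off, strand))
    return out


def _sp(seq, sid="q1", **kw):
    return Spacer(spacer_id=sid, seq=seq, **kw)


class TestDedupeSpacers:
    def test_exact_duplicates_collapse(self):
        sps = [_sp("ACGTACGTACGTACGTACGT", "a"), _sp("ACGTACGTACGTACGTACGT", "b")]
        assert len(dedupe_spacers(sps)) == 1

    def test_reverse_complement_duplicates_collapse(self, rng):
        s = random_dna(rng, 32)
        out = dedupe_spacers([_sp(s, "a"), _sp(revcomp(s), "b")])
        assert len(out) == 1
        assert out[0].seq == canonical(s)

    def test_distinct_set_unchanged(self, rng):
        sps = [_sp(random_dna(rng, 32), f"q{i}") for i in range(5)]
        assert len(dedupe_spacers(sps)) == 5


class TestMatchSpacersToReference:
    def test_planted_spacer_found_at_100_percent(self, rng):
        sp = random_dna(rng, 32)
        ref = random_dna(rng, 400) + sp + random_dna(rng, 400)
        matches = match_spacers_to_reference([_sp(sp)], {"r": ref})
        exact = [m for m in matches if m.identity == 100.0]
        assert len(exact) == 1
        assert (exact[0].start, exact[0].end, exact[0].strand) == (400, 432, "+")

    def test_seven_substitutions_fall_below_80_percent(self, rng):
        # 25/32 = 78.1% is discarded; 26/32 = 81.25% is retained
        sp = random_dna(rng, 32)
        for n_subs, expected in [(7, 0), (6, 1)]:
            target = list(sp)
            for i in range(0, 4 * n_subs, 4):
                target[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[target[i]]
            ref = random_dna(rng, 200) + "".join(target) + random_dna(rng, 200)
            matches = match_spacers_to_reference([_sp(sp)], {"r": ref})
            hits = [m for m in matches if m.start == 200]
            assert len(hits) == expected, f"{n_subs} substitutions"
            assert len(hits) == len(
                [1 for off, _ in brute_force_matches(sp, ref, 0.80) if off == 200]
            )

    def test_self_hits_inside_source_array_removed(self, rng):
        sp = random_dna(rng, 32)
        ref = random_dna(rng, 100) + sp + random_dna(rng, 100)
        query = _sp(sp, "q1", strain_id="s", contig_id="r", array_start=90, array_end=140)
        assert match_spacers_to_reference([query], {"r": ref}) == []
        elsewhere = _sp(sp, "q2", strain_id="s", contig_id="r", array_start=150, array_end=200)
        assert len(match_spacers_to_reference([elsewhere], {"r": ref})) == 1

    def test_strand_symmetry(self, rng):
        sp = random_dna(rng, 32)
        ref = random_dna(rng, 300) + sp + random_dna(rng, 300)
        fwd = match_spacers_to_reference([_sp(sp)], {"r": ref})
        rev = match_spacers_to_reference([_sp(sp)], {"r": revcomp(ref)})
        n = len(ref)
        mirrored = {(n - m.end, n - m.start, {"+": "-", "-": "+"}[m.strand], m.identity) for m in rev}
        assert {(m.start, m.end, m.strand, m.identity) for m in fwd} == mirrored

    def test_lowering_threshold_never_removes_matches(self, rng):
        sps = [_sp(random_dna(rng, 32), f"q{i}") for i in range(5)]
        ref = {"r": random_dna(rng, 3000) + sps[0].seq + random_dna(rng, 100)}
        strict = match_spacers_to_reference(sps, ref, min_identity=0.90)
        loose = match_spacers_to_reference(sps, ref, min_identity=0.80)
        strict_keys = {(m.query_id, m.target_id, m.start, m.strand) for m in strict}
        loose_keys = {(m.query_id, m.target_id, m.start, m.strand) for m in loose}
        assert strict_keys <= loose_keys

    def test_oracle_equivalence_on_random_panel(self, rng):
        ref = random_dna(rng, 5000)
        spacers = [_sp(random_dna(rng, 32), f"q{i}") for i in range(20)]
        # plant some degraded copies so hits exist
        ref = ref[:1000] + spacers[0].seq + ref[1000:3000] + revcomp(spacers[1].seq) + ref[3000:]
        matches = match_spacers_to_reference(spacers, {"r": ref}, min_identity=0.80)
        got = {(m.query_id, m.start, m.strand) for m in matches}
        want = set()
        for sp in spacers:
            for off, strand in brute_force_matches(sp.seq, ref, 0.80):
                want.add((sp.spacer_id, off, strand))
        assert got == want

    def test_invalid_threshold_rejected(self, rng):
        sp = [_sp(random_dna(rng, 32))]
        for bad in (0.5, 0.0, 1.2):
            with pytest.raises(ValueError):
                match_spacers_to_reference(sp, {"r": random_dna(rng, 100)}, min_identity=bad)

    def test_gapped_mode_finds_single_deletion_target(self, rng):
        sp = random_dna(rng, 32)
        target = sp[:15] + sp[16:]  # one base deleted
        ref = random_dna(rng, 200) + target + random_dna(rng, 200)
        ungapped = match_spacers_to_reference([_sp(sp)], {"r": ref}, mode="ungapped")
        gapped = match_spacers_to_reference([_sp(sp)], {"r": ref}, mode="gapped")
        assert any(m.identity >= 96 for m in gapped)
        assert all(m.identity < 96 for m in ungapped)


class TestSharingMatrix:
    def test_planted_sharing_counts(self, rng):
        shared = [random_dna(rng, 32) for _ in range(2)]
        a = [_sp(s, f"a{i}", strain_id="A") for i, s in enumerate(shared)] + [
            _sp(random_dna(rng, 32), f"a{i+2}", strain_id="A") for i in range(3)
        ]
        b = [_sp(revcomp(s), f"b{i}", strain_id="B") for i, s in enumerate(shared)] + [
            _sp(random_dna(rng, 32), f"b{i+2}", strain_id="B") for i in range(4)
        ]
        summary = sharing_matrix({"A": a, "B": b})
        assert summary.counts.loc["A", "B"] == 2
        assert summary.counts.loc["B", "A"] == 2
        assert summary.totals["A"] == 5
        assert summary.totals["B"] == 6

    def test_identical_strains_share_everything(self, rng):
        sps = [random_dna(rng, 32) for _ in range(4)]
        a = [_sp(s, f"a{i}", strain_id="A") for i, s in enumerate(sps)]
        b = [_sp(s, f"b{i}", strain_id="B") for i, s in enumerate(sps)]
        summary = sharing_matrix({"A": a, "B": b})
        assert summary.counts.loc["A", "B"] == 4

    def test_disjoint_random_sets_share_nothing(self, rng):
        a = [_sp(random_dna(rng, 32), f"a{i}", strain_id="A") for i in range(6)]
        b = [_sp(random_dna(rng, 32), f"b{i}", strain_id="B") for i in range(6)]
        summary = sharing_matrix({"A": a, "B": b})
        assert summary.counts.loc["A", "B"] == 0
        assert summary.counts.loc["B", "A"] == 0

    def test_exact_mode_reduces_to_equality(self, rng):
        s = random_dna(rng, 32)
        near = s[:1] + ("A" if s[1] != "A" else "C") + s[2:]
        a = [_sp(s, "a0", strain_id="A")]
        b = [_sp(near, "b0", strain_id="B")]
        assert sharing_matrix({"A": a, "B": b}, min_identity=1.0).counts.loc["A", "B"] == 0
        assert sharing_matrix({"A": a, "B": b}, min_identity=0.80).counts.loc["A", "B"] == 1

    def test_single_strain_rejected(self, rng):
        with pytest.raises(ValueError):
            sharing_matrix({"A": [_sp(random_dna(rng, 32), strain_id="A")]})
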