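"""Repeat typing and hairpin analysis against brute-force oracles."""

import pytest

from crisprcomp.array_detection import CrisprArray
from crisprcomp.repeat_typing import (
    DEFAULT_IIC_REPEAT,
    RepeatCatalog,
    build_ie_repeat,
    classify_repeat,
    fold_hairpin,
    levenshtein,
    tetraloop_census,
)
from crisprcomp.seqs import random_dna, revcomp

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_force_hairpin(repeat: str, min_stem: int = 5, min_loop: int = 3):
    """Exhaustive search over all arm pairs; returns (stem, loop_len, a, b_end)."""
    n = len(repeat)
    best = None
    for a in range(n):
        for s in range(min_stem, n // 2 + 1):
            if a + s > n:
                break
            for b in range(a + s + min_loop, n - s + 1):
                arm5 = repeat[a : a + s]
                arm3 = repeat[b : b + s]
                if arm3 == revcomp(arm5):
                    loop = b - (a + s)
                    key = (s, -loop, -a)
                    if best is None or key > best[0]:
                        best = (key, (s, loop, a, b + s))
    return None if best is None else best[1]


def test_levenshtein_agrees_with_dp_oracle(rng):
    for _ in range(1000):
        a = random_dna(rng, int(rng.integers(5, 40)))
        b = random_dna(rng, int(rng.integers(5, 40)))
        assert levenshtein(a, b) == dp_levenshtein(a, b)


class TestClassifyRepeat:
    def test_exact_catalog_repeat_is_accepted_at_distance_zero(self):
        cat = RepeatCatalog.default()
        cls = classify_repeat(cat.entries[0][0], cat)
        assert cls.edit_distance == 0
        assert cls.accepted
        assert cls.subtype == "I-E"

    def test_four_edits_is_still_accepted(self, rng):
        cat = RepeatCatalog.default()
        base = cat.entries[0][0]
        # swap the tetraloop for a disjoint one: exactly 4 substitutions
        mutated = base[:12] + "ACAA" + base[16:]
        assert dp_levenshtein(base, mutated) == 4
        cls = classify_repeat(mutated, cat)
        assert cls.edit_distance == 4
        assert cls.accepted

    def test_distant_random_repeat_is_rejected(self, rng):
        cat = RepeatCatalog.default()
        while True:
            q = random_dna(rng, 29)
            dmin = min(
                min(dp_levenshtein(q, e[0]), dp_levenshtein(revcomp(q), e[0]))
                for e in cat.entries
            )
            if dmin >= 5:
                break
        cls = classify_repeat(q, cat)
        assert cls.edit_distance == dmin
        assert not cls.accepted

    def test_strand_invariance(self, rng):
        cat = RepeatCatalog.default()
        for _ in range(25):
            q = random_dna(rng, 29)
            a = classify_repeat(q, cat)
            b = classify_repeat(revcomp(q), cat)
            assert a.edit_distance == b.edit_distance
            assert a.accepted == b.accepted

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            RepeatCatalog(entries=[])

    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            classify_repeat("ACGTACGTACGT", RepeatCatalog.default())


class TestFoldHairpin:
    def test_worked_tetraloop_example(self):
        # nominal structure: TATT | GCCGAGC | TTCA | GCTCGGC | AGAAC, but the
        # outermost tail bases (T...A) also pair, so the true optimum under
        # the exact-complement rule is an 8-bp stem with the same TTCA loop
        # (confirmed by the exhaustive oracle below)
        repeat = "TATT" + "GCCGAGC" + "TTCA" + "GCTCGGC" + "AGAAC"
        hp = fold_hairpin(repeat)
        want = brute_force_hairpin(repeat)
        assert (hp.stem_len, len(hp.loop_seq), hp.arm5_start) == (want[0], want[1], want[2])
        assert hp.stem_len == 8
        assert hp.loop_seq == "TTCA"
        assert hp.tail5 == "TAT"
        assert hp.tail3 == "GAAC"

    def test_homopolymer_cannot_fold(self):
        assert fold_hairpin("A" * 20) is None

    def test_agrees_with_exhaustive_search_on_random_repeats(self, rng):
        for _ in range(300):
            rep = random_dna(rng, int(rng.integers(16, 41)))
            got = fold_hairpin(rep)
            want = brute_force_hairpin(rep)
            if want is None:
                assert got is None
            else:
                s, loop, a, b_end = want
                assert (got.stem_len, len(got.loop_seq), got.arm5_start, got.arm3_end) == (
                    s, loop, a, b_end
                )

    def test_planted_ie_repeats_have_their_tetraloop(self):
        for loop in ("GTTC", "TTCG", "GAAA", "CTAG"):
            hp = fold_hairpin(build_ie_repeat(loop))
            assert hp is not None
            assert hp.loop_seq == loop
            assert len(hp.loop_seq) == 4


def _array(strain, context, repeat, system_type="I-E"):
    return CrisprArray(
        strain_id=strain, contig_id="c", start=0, end=1,
        repeats=[repeat], spacers=[], consensus_repeat=repeat,
        system_type=system_type, context=context,
    )


class TestTetraloopCensus:
    def test_counts_distinct_loops_separately(self):
        arrays = [
            _array("s1", "canonical", build_ie_repeat("TTCA")),
            _array("s1", "canonical", build_ie_repeat("TTCG")),
        ]
        out = tetraloop_census(arrays)
        assert len(out) == 2
        assert sorted(out.tetraloop) == ["TTCA", "TTCG"]
        assert list(out["count"]) == [1, 1]

    def test_contexts_separate_per_planted_truth(self, full_panel):
        truth = full_panel.truth.arrays
        arrays = [
            _array(r.strain_id, r.context, r.repeat)
            for r in truth.itertuples()
            if r.system_type == "I-E"
        ]
        census = tetraloop_census(arrays)
        want = (
            truth[truth.system_type == "I-E"]
            .groupby(["strain_id", "context", "tetraloop"])
            .size()
        )
        assert census["count"].sum() == want.sum()
        for _, row in census.iterrows():
            assert want[(row["strain_id"], row["context"], row["tetraloop"])] == row["count"]

    def test_unfoldable_repeat_tallied_as_na(self):
        arrays = [_array("s1", "canonical", "A" * 29)]
        out = tetraloop_census(arrays)
        assert list(out.tetraloop) == ["NA"]

    def test_empty_input_gives_empty_table(self):
        assert len(tetraloop_census([])) == 0

    def test_non_ie_arrays_are_ignored(self):
        arrays = [_array("s1", "canonical", DEFAULT_IIC_REPEAT, system_type="II-C")]
        assert len(tetraloop_census(arrays)) == 0
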