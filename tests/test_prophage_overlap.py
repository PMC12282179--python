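"""Interval attribution: padding, overlap counting, genic split, edge export."""

import pandas as pd
import pytest

from crisprcomp.prophage_overlap import (
    ProphageRegion,
    attribute_matches,
    edge_table,
    export_edges,
    genic_summary,
    pad_interval,
)
from crisprcomp.spacer_matching import SpacerMatch


def _match(qid, start, end, identity=100.0, target="S1_c1"):
    return SpacerMatch(query_id=qid, target_id=target, start=start, end=end,
                       strand="+", identity=identity)


def _region(start, end, completeness="intact", rid="P1", target="S1_c1"):
    return ProphageRegion(strain_id="S1", contig_id=target, start=start, end=end,
                          completeness=completeness, region_id=rid)


class TestPadding:
    def test_32bp_each_side(self):
        assert pad_interval(100, 132, 32) == (68, 164)

    def test_clipped_at_contig_start_and_end(self):
        assert pad_interval(10, 40, 32, contig_len=60) == (0, 60)

    def test_pad_zero_is_identity(self):
        assert pad_interval(100, 132, 0) == (100, 132)


class TestOverlapCounting:
    def test_one_bp_overlap_counts(self):
        m = _match("a|x", 100, 132)
        # padded to [68, 164); region ending at 69 overlaps by 1 bp
        res = attribute_matches([m], [_region(50, 69)], [], [])
        assert len(res.prophage) == 1

    def test_match_30bp_short_counts_after_padding(self):
        m = _match("a|x", 100, 132)
        res = attribute_matches([m], [_region(162, 1200)], [], [])
        assert len(res.prophage) == 1
        res0 = attribute_matches([m], [_region(165, 1200)], [], [], pad=0)
        assert len(res0.prophage) == 0

    def test_non_overlapping_match_passes_to_genic_attribution(self):
        m = _match("a|x", 100, 132)
        res = attribute_matches([m], [_region(5000, 7000)], [], [("S1_c1", 90, 200)])
        assert res.prophage == []
        assert len(res.genic) == 1

    def test_brute_force_per_base_oracle_on_random_fixtures(self, rng):
        """Counts equal a per-base membership scan on 100 random layouts."""
        for trial in range(100):
            contig_len = 2000
            regions = []
            cursor = 0
            rid = 0
            while cursor < contig_len - 200:
                start = cursor + int(rng.integers(10, 120))
                end = start + int(rng.integers(50, 200))
                if end >= contig_len:
                    break
                regions.append(
                    ProphageRegion("S1", "S1_c1", start, end,
                                   ["intact", "incomplete", "questionable"][rid % 3],
                                   region_id=f"P{rid}")
                )
                rid += 1
                cursor = end
            matches = []
            for i in range(20):
                s = int(rng.integers(0, contig_len - 32))
                matches.append(_match(f"q{i}|x", s, s + 32))
            pad = int(rng.integers(0, 40))
            res = attribute_matches(matches, regions, [], [], pad=pad,
                                    contig_lengths={"S1_c1": contig_len})
            got = {}
            for m, r in res.prophage:
                got[r.region_id] = got.get(r.region_id, 0) + 1
            # oracle: per-base membership
            want = {}
            for m in matches:
                ps, pe = max(0, m.start - pad), min(contig_len, m.end + pad)
                for r in regions:
                    if any(r.start <= b < r.end for b in range(ps, pe)):
                        want[r.region_id] = want.get(r.region_id, 0) + 1
            assert got == want, f"trial {trial}"

    def test_match_overlapping_two_regions_counts_once_per_region(self):
        m = _match("a|x", 100, 132)
        regions = [_region(50, 110, rid="P1"), _region(120, 180, rid="P2")]
        res = attribute_matches([m], regions, [], [], pad=0)
        assert {r.region_id for _, r in res.prophage} == {"P1", "P2"}
        # but the match is attributed (partitioned) once
        assert len({id(mm) for mm, _ in res.prophage}) == 1


class TestGenicAttribution:
    def test_match_inside_own_array_dropped_as_self(self):
        m = _match("a|x", 100, 132)
        res = attribute_matches([m], [], [("S1_c1", 50, 200)], [])
        assert res.self_dropped == [m]
        assert res.genic == [] and res.intergenic == []

    def test_match_inside_gene_is_genic_else_intergenic(self):
        inside = _match("a|x", 100, 132)
        outside = _match("b|x", 500, 532)
        res = attribute_matches([inside, outside], [], [], [("S1_c1", 90, 200)])
        assert res.genic == [inside]
        assert res.intergenic == [outside]

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        matches = [_match(f"q{i}|x", int(rng.integers(0, 3000)), 0) for i in range(50)]
        for m in matches:
            m.end = m.start + 32
        regions = [_region(500, 900)]
        arrays = [("S1_c1", 1500, 1800)]
        genes = [("S1_c1", 2200, 2600)]
        res = attribute_matches(matches, regions, arrays, genes, pad=32)
        attributed = {id(m) for m, _ in res.prophage}
        buckets = [attributed, {id(m) for m in res.self_dropped},
                   {id(m) for m in res.genic}, {id(m) for m in res.intergenic}]
        union = set().union(*buckets)
        assert union == {id(m) for m in matches}
        assert sum(len(b) for b in buckets) == len(matches)

    def test_unique_and_total_tallies(self):
        matches = [_match("a|x", 100, 132), _match("a|x", 500, 532), _match("b|x", 600, 632)]
        res = attribute_matches(matches, [], [], [("S1_c1", 90, 700)])
        s = genic_summary(res)
        assert s["genic_total"] == 3
        assert s["genic_unique"] == 2


class TestEdgeExport:
    def test_mean_identity_and_count(self):
        matches = [
            _match("Q|1", 100, 132, identity=100.0),
            _match("Q|2", 200, 232, identity=90.0),
            _match("Q|3", 300, 332, identity=95.0),
        ]
        res = attribute_matches(matches, [_region(50, 400)], [], [])
        edges = edge_table(res)
        assert len(edges) == 1
        row = edges.iloc[0]
        assert row.source_id == "Q"
        assert row.n_matches == 3
        assert row.mean_identity == pytest.approx(95.0)
        assert row.completeness_class == "intact"

    def test_empty_input_gives_headed_empty_files(self, tmp_path):
        res = attribute_matches([], [], [], [])
        p1, p2 = export_edges(edge_table(res), tmp_path)
        for p in (p1, p2):
            df = pd.read_csv(p, sep="\t")
            assert list(df.columns) == [
                "source_id", "target_id", "completeness_class", "n_matches", "mean_identity"
            ]
            assert len(df) == 0

    def test_export_is_byte_deterministic(self, tmp_path):
        matches = [_match("Q|1", 100, 132, identity=88.0)]
        regions = [_region(50, 400, completeness="questionable")]
        outs = []
        for sub in ("a", "b"):
            res = attribute_matches(list(matches), list(regions), [], [])
            p1, p2 = export_edges(edge_table(res), tmp_path / sub)
            outs.append((p1.read_bytes(), p2.read_bytes()))
        assert outs[0] == outs[1]
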