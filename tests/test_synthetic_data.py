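"""Generator contracts: determinism, planted-truth bookkeeping, read simulation."""

import numpy as np
import pytest
from scipy import stats as sstats

from crisprcomp import io as cio
from crisprcomp.seqs import hamming_identity, revcomp
from crisprcomp.synthetic_data import (
    ArrayPlan,
    ProphagePlan,
    StrainPlan,
    build_strain_panel,
    demo_panel_plans,
    make_host_genome,
    simulate_reads,
)


def _one_strain_plan(**kwargs):
    defaults = dict(
        strain_id="T1",
        n_contigs=2,
        contig_lengths=[30000, 15000],
        arrays=[
            ArrayPlan("I-E", "canonical", 5),
            ArrayPlan("I-E", "orphan", 4),
            ArrayPlan("II-C", "canonical", 3),
        ],
        prophages=[ProphagePlan("T1_P1", 4000, "intact")],
        genes=3,
    )
    defaults.update(kwargs)
    return StrainPlan(**defaults)


def test_same_plans_same_seed_are_byte_identical(tmp_path):
    for sub in ("a", "b"):
        panel = build_strain_panel([_one_strain_plan()], seed=42)
        panel.write(tmp_path / sub)
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name


def test_truth_table_conserves_planted_counts():
    plan = _one_strain_plan()
    panel = build_strain_panel([plan], seed=1)
    assert len(panel.truth.arrays) == 3
    assert panel.truth.arrays.n_spacers.sum() == 12
    assert len(panel.truth.spacers) == 12
    assert len(panel.truth.prophages) == 1
    # every feature appears exactly once
    assert not panel.truth.arrays.duplicated(["contig_id", "start"]).any()


def test_gff_coordinates_match_truth(tmp_path):
    panel = build_strain_panel([_one_strain_plan()], seed=3)
    panel.write(tmp_path)
    feats = cio.read_gff(tmp_path / "T1.gff3", ftype="gene")
    truth = panel.truth.genes
    assert len(feats) == len(truth)
    truth_set = {(r.contig_id, r.start, r.end) for r in truth.itertuples()}
    assert {(f.contig_id, f.start, f.end) for f in feats} == truth_set


def test_planted_context_distances_respect_500bp_rule():
    panel = build_strain_panel([_one_strain_plan()], seed=4)
    genes = panel.truth.genes
    cas = genes[genes.is_cas]
    for arr in panel.truth.arrays.itertuples():
        gaps = []
        for g in cas[cas.contig_id == arr.contig_id].itertuples():
            if g.end <= arr.start:
                gaps.append(arr.start - g.end)
            elif arr.end <= g.start:
                gaps.append(g.start - arr.end)
            else:
                gaps.append(0)
        if arr.context == "canonical":
            assert gaps and min(gaps) <= 500
        else:
            assert not gaps or min(gaps) > 500


def test_prophage_spacers_at_zero_noise_are_exact_copies():
    plan = _one_strain_plan(
        arrays=[
            ArrayPlan(
                "I-E",
                "canonical",
                4,
                spacer_sources=["prophage:T1_P1"] * 2 + ["random"] * 2,
            )
        ]
    )
    panel = build_strain_panel([plan], seed=5)
    contigs = panel.assemblies["T1"]
    proph = panel.truth.prophages.iloc[0]
    donor = contigs[proph.contig_id][proph.start : proph.end]
    sourced = panel.truth.spacers[panel.truth.spacers.source != "random"]
    assert len(sourced) == 2
    for sp in sourced.itertuples():
        assert sp.seq in donor or revcomp(sp.seq) in donor
        window = donor[sp.proto_start : sp.proto_end]
        assert sp.seq == (window if sp.proto_strand == "+" else revcomp(window))


def test_mutated_prophage_spacers_match_binomial_identity():
    """1,000 planted spacers at per-base rate 1/16: mean identity ~93.75%."""
    rate = 0.0625
    plans = []
    for i in range(25):
        sid = f"M{i:02d}"
        plans.append(
            StrainPlan(
                strain_id=sid,
                n_contigs=1,
                contig_lengths=[80000],
                arrays=[
                    ArrayPlan(
                        "I-E",
                        "canonical",
                        40,
                        spacer_sources=[f"prophage:{sid}_P1"] * 40,
                        mutation_rate=rate,
                    )
                ],
                prophages=[ProphagePlan(f"{sid}_P1", 4000, "intact")],
                genes=0,
            )
        )
    panel = build_strain_panel(plans, seed=6)
    idents = []
    proph_seq = {}
    for p in panel.truth.prophages.itertuples():
        proph_seq[p.prophage_id] = panel.assemblies[p.strain_id][p.contig_id][p.start : p.end]
    for sp in panel.truth.spacers.itertuples():
        window = proph_seq[sp.prophage_id][sp.proto_start : sp.proto_end]
        if sp.proto_strand == "-":
            window = revcomp(window)
        idents.append(hamming_identity(sp.seq, window))
    assert len(idents) == 1000
    assert abs(np.mean(idents) - (1 - rate)) < 0.01


def test_overfull_plan_is_rejected_with_message():
    plan = _one_strain_plan(contig_lengths=[3000, 1000])
    with pytest.raises(ValueError, match="exceed contig length"):
        build_strain_panel([plan], seed=1)


def test_shared_spacer_sources_are_exact_across_strains():
    panel = build_strain_panel(demo_panel_plans(8, seed=7), seed=11)
    sp = panel.truth.spacers
    shared = sp[sp.source.str.startswith("shared:")]
    assert len(shared) > 0
    for row in shared.itertuples():
        strain, ai, si = row.source.split(":")[1:]
        donor = sp[
            (sp.strain_id == strain)
            & (sp.array_index == int(ai))
            & (sp.spacer_index == int(si))
        ]
        assert donor.iloc[0].seq == row.seq


@pytest.fixture(scope="module")
def community():
    panel = build_strain_panel(demo_panel_plans(2, seed=7), seed=11)
    comm = [(s, panel.assemblies[s], 0.5) for s in panel.assemblies]
    host = make_host_genome(
        5000, [panel.assemblies[s] for s in panel.assemblies], seed=2
    )
    return comm, host


class TestSimulateReads:
    def test_zero_host_fraction_labels_no_host_pairs(self, community):
        comm, host = community
        _, truth = simulate_reads(comm, host, 0.0, 100, 300, 0.0, seed=1)
        assert not truth.is_host.any()

    def test_error_free_reads_are_verbatim_substrings(self, community):
        comm, host = community
        reads, truth = simulate_reads(comm, host, 0.2, 100, 200, 0.0, seed=2)
        genomes = {name: assembly for name, assembly, _ in comm}
        genomes["host"] = {"host": host}
        for (pid, r1, r2), row in zip(reads, truth.itertuples()):
            src = genomes[row.source][row.contig_id]
            for read in (r1, r2):
                assert read in src or revcomp(read) in src

    def test_host_fraction_within_binomial_interval(self, community):
        comm, host = community
        n = 10_000
        _, truth = simulate_reads(comm, host, 0.3, 100, n, 0.0, seed=3)
        lo, hi = sstats.binom.interval(0.99, n, 0.3)
        assert lo <= truth.is_host.sum() <= hi

    def test_read_len_longer_than_shortest_contig_rejected(self, community):
        comm, host = community
        with pytest.raises(ValueError, match="shortest contig"):
            simulate_reads(comm, {"host": host}["host"], 0.1, 9000, 10, 0.0, seed=4)

    def test_host_genome_shares_no_31mer_with_community(self, community):
        comm, host = community
        kmers = set()
        for _, assembly, _ in comm:
            for seq in assembly.values():
                for i in range(len(seq) - 31 + 1):
                    kmers.add(seq[i : i + 31])
                    kmers.add(revcomp(seq[i : i + 31]))
        assert not any(host[i : i + 31] in kmers for i in range(len(host) - 30))
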