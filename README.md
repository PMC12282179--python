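# crisprcomp

Comparative characterization of bacterial CRISPR-Cas systems, built for
the kind of question a microbial-genomics group asks about a clade of
closely related strains (the motivating system is an acetic acid
bacterium of the honey-bee niche, with co-occurring type I-E and II-C
systems): which strains carry which CRISPR types, are arrays adjacent
to their Cas operon or orphaned elsewhere in the genome, how variable
are the repeat hairpin tetraloops, how many spacers do related strains
share, and do spacers point back at prophages integrated in the same
clade?

The package covers the whole comparative workflow as a library plus a
thin CLI:

- **Array detection** (`array_detection`) — CRT-style repeat-spacer
  structure finding: exact k-mer seeds at spacer-compatible distances,
  column-agreement boundary extension, and guards against tandem
  repeats and degenerate repeat sets.
- **Repeat typing and hairpin analysis** (`repeat_typing`) — nearest
  catalog entry by strand-aware Levenshtein distance (accepted at ≤ 4
  edits), plus an exact-complement stem-loop search that extracts the
  I-E tetraloop.
- **Canonical/orphan context** (`array_context`) — bedtools-closest
  gap semantics against annotated Cas genes; canonical iff the gap is
  ≤ 500 bp on the same contig.
- **Read-based spacer mining** (`read_spacers`) — crass-style recovery
  of spacers from unassembled reads (23-mer recurring ≥ 26 bp apart),
  host read-pair decontamination with both-unmapped keep semantics,
  group merging across read files, and a rescue sweep for known
  repeats.
- **Spacer matching** (`spacer_matching`) — exhaustive both-strand
  placement of spacers on references at ≥ 80% identity (identity =
  matches / spacer length), self-hit removal, dedup of exact and
  reverse-complement copies, and cross-strain sharing matrices.
- **Prophage attribution** (`prophage_overlap`) — 32-bp padded
  interval intersection against prophage calls (intact vs
  incomplete/questionable pooled), then subtract-self and genic vs
  intergenic splitting; Cytoscape-ready edge tables.
- **Statistics** (`stats`) — Wilcoxon-Mann-Whitney test (exact by
  enumeration for pooled n ≤ 12, otherwise tie- and
  continuity-corrected normal approximation) and Monte-Carlo power
  under `lnorm(meanlog, sdlog)` / `exp(rate)` sampling.
- **Synthetic panels** (`synthetic_data`) — strain panels with planted
  arrays (both types, both contexts), Cas operons, decoy genes,
  prophages that donate protospacers, shared spacers between strains,
  and paired reads with a host decoy — every feature recorded in a
  truth table so each stage is testable end to end.

## The statistics in brief

For samples `x (n1)` and `y (n2)` the test statistic is the
Mann-Whitney count `U = #{(i,j): x_i > y_j} + ½·#{x_i = y_j}`.  Power
for a planned comparison is estimated by simulation: draw `n1` values
from one fitted distribution and `n2` from another, test at level α,
and report the rejection fraction over 10,000 replicates.  With the
fitted spacer-count distributions used in the reference analysis —
`lnorm(2.7365304, 0.6243374)` vs `exp(0.0323741)` at group sizes 13/18,
and `exp(0.03865337)` vs `lnorm(1.5345364, 0.6981095)` at 31/9 — this
yields ≈ 11% and ≈ 90% power respectively.

## Worked example

```python
from crisprcomp import (
    build_strain_panel, demo_panel_plans, strain_scan, classify_contexts,
    CasGene, wmw_power, PowerSpec, DistributionSpec,
)
from crisprcomp.repeat_typing import assign_types, fold_hairpin

panel = build_strain_panel(demo_panel_plans(4, seed=7), seed=11)
strain = "S02"
arrays = strain_scan(panel.assemblies[strain], strain_id=strain)
assign_types(arrays)
cas = [CasGene(f.contig_id, f.start, f.end, f.strand, f.name)
       for f in panel.gff[strain]
       if f.ftype == "gene" and f.name.startswith(("cas", "cse"))]
classify_contexts(arrays, cas)
for a in arrays:
    hp = fold_hairpin(a.consensus_repeat)
    print(f"{a.contig_id}:{a.start}-{a.end}  {a.system_type:5s} {a.context:9s} "
          f"{a.n_spacers:3d} spacers  loop {hp.loop_seq if hp else '-'}")

power = wmw_power(PowerSpec(
    n1=13, n2=18,
    dist1=DistributionSpec("lnorm", (2.7365304, 0.6243374)),
    dist2=DistributionSpec("exp", (0.0323741,)),
    alpha=0.05, reps=10_000, seed=1,
))
print(f"canonical-vs-orphan WMW power: {power:.3f}")
```

prints

```
S02_c1:5807-6934  I-E   canonical   18 spacers  loop GTTC
S02_c2:230-2394  I-E   orphan     35 spacers  loop TTCG
canonical-vs-orphan WMW power: 0.109
```

i.e. strain S02 carries a canonical I-E array (18 spacers, tetraloop
GTTC) right after its Cas operon on contig 1 and a larger orphan I-E
array (35 spacers, tetraloop TTCG) on contig 2 — the two-array
configuration with context-specific tetraloops that the panel
generator plants — and a 13-vs-18 comparison under those fitted
distributions would only reach ~11% power.

The same workflow runs from the shell:

```
crisprcomp run-all examples/demo.cfg
```

which simulates a panel, detects and types arrays, labels contexts,
mines reads, matches spacers, attributes prophage overlaps, and writes
per-stage TSVs plus a manifest under `demo_output/`.

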