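# Methods

This note documents the models, algorithms and design choices behind
`crisprcomp`, in the order the pipeline runs them, together with what
the synthetic panels do and do not emulate.

## Array detection

The detector looks for the defining structure of a CRISPR array — a
near-identical unit of 19–38 bp recurring at 19–48 bp intervals —
rather than for any particular sequence.

1. **Seeding.** Every exact `seed_k`-mer (default 23) recurrence whose
   start-to-start distances lie in `[min_repeat + min_spacer,
   max_repeat + max_spacer]` seeds a candidate chain; scanning is
   left-to-right, so placement is leftmost-maximal.  K-mers containing
   `N` never seed and candidate repeats containing `N` are dropped
   (`N` never matches anything).
2. **Boundary extension.** The repeat unit grows one column at a time
   on either side while at least 75% of the copies agree on the new
   column, the unit stays within the length cap, and no spacer would
   shrink below its minimum.
3. **Unit growth.** Additional copies beyond either end are accepted
   when a window at spacer-compatible distance matches the running
   consensus within `max_repeat_edits` (default 3), fewest edits first,
   leftmost on ties — this is what makes reported arrays maximal.
4. **Refinement.** Two polish passes address a failure mode of seeded
   detection: a seed can anchor on a flank base coincidentally shared
   by a few units, dragging the boundary or individual copies off by a
   base.  (a) Edge columns are re-judged over the *full* unit set and
   trimmed back where agreement falls below 75%, then extension is
   re-attempted; (b) each copy is slid within ±4 bp to its minimal
   edit distance against the consensus (ties to the smallest shift).
5. **Guards.** An array is rejected when any copy exceeds
   `max_repeat_edits` from the consensus (degenerate repeat set) or
   when mean pairwise spacer identity exceeds 60% (a tandem repeat
   masquerading as repeat-plus-spacer).  Random 32-mers have
   Levenshtein identity ≈ 0.41 ± 0.05 (empirical max ≈ 0.59 over
   2,000 draws), so genuine spacer sets clear the 60% bar comfortably.

Consensus calling is per-column majority over flush-left-aligned
copies, ties to the lexicographically smaller base; consensus length is
the median copy length.

Every reported array satisfies, by construction and assertion, the
reconstruction invariant: repeats and spacers concatenate exactly to
the contig substring `[start, end)`.

## Repeat typing and the hairpin model

Typing is nearest-neighbour by unit-cost Levenshtein distance over a
repeat catalog and both query strands, accepted at ≤ 4 edits.  The
shipped default catalog holds two synthetic representative repeats
(the same base sequences the panel generator plants): an I-E-style
palindrome (5-nt tail, 7-bp arms, 4-nt loop, 6-nt tail; 29 bp) and a
II-C-style repeat with no designed structure.  Real analyses should
supply their own catalog TSV.  A machine-learned classification score
is deliberately out of scope: the edit-distance rule is reproducible
and auditable, and a probability score from an external model would
not be.

The hairpin model is exact-complement pairing only — contiguous arms,
no G·U wobble, no bulges — which is sufficient for the palindromic
repeats modelled here and fully checkable by brute force.  Among all
arm pairs with stem ≥ `min_stem` (default 5) and loop ≥ `min_loop`
(default 3; shorter loops are sterically impossible, and without this
floor any tetraloop whose outer bases happen to complement would
"fold" into a 2-nt loop), the fold maximises stem length, then
minimises loop length, then takes the leftmost 5' arm.  The 4-nt loop
of the best fold of an I-E repeat is its tetraloop; arrays whose
repeat does not fold are counted under `NA` in the census.

A II-C extra: a tracrRNA-like anti-repeat can be annotated as the
longest ≥ 20 bp reverse-complement match of the repeat within 500 bp
upstream of the Cas operon.

## Canonical vs orphan context

Distance is the bedtools-closest convention — bases strictly between
intervals, 0 for overlap or abutment — measured against every
annotated Cas gene on the same contig (an optional mode restricts to a
name pattern).  Canonical iff gap ≤ 500 bp; orphan on a strict
inequality or when no Cas gene shares the contig.  The boundary is
exact: gap 500 is canonical, 501 is orphan.

## Read-based spacer mining

A read is CRISPR-bearing when some 23-mer occurs twice with starts
≥ 26 bp apart.  Reads are clustered across the sample by shared
recurring k-mers (union-find, strand-canonical); per cluster the most
frequent k-mer anchors a column-voting consensus in which every anchor
occurrence in every member read votes, columns extending outward while
≥ 75% of ≥ 2 votes agree — the same agreement rule as assembly-side
boundary extension.  Repeat instances (full, or read-end partials
overlapping ≥ 8 bp) are then located per read and spacers are the
inter-instance sequences; only repeat-bounded sequences become full
spacers.  Groups need ≥ 2 repeat instances and ≥ 2 distinct spacers;
spacers shorter than 16 bp are discarded as unmappable fragments.

Merging consolidates groups with identical or reverse-complement
consensus repeats onto the lexicographically smaller strand, unions
spacers with exact-duplicate removal, and lets full spacers absorb
partial ones that are their substrings.  The rescue pass sweeps reads
for repeats already known from assemblies and contributes terminal
flanks as *partial* spacers (flagged as such, since a flank may extend
past the true spacer into non-array sequence at array edges); recovery
claims in the tests are therefore made on full, repeat-bounded
spacers.

Host decontamination keeps a pair only when *neither* mate maps to the
host.  Mapping is exact 31-mer sharing with the host genome (either
strand) — a desk-scale surrogate for a read aligner that is exact for
substitution-free host reads and swappable behind the same contract.
The generator's host decoy is built with 31-mer exclusion against the
community, so the filter's completeness is testable.

## Spacer matching

The matching contract is exhaustive rather than heuristic: every
placement of every spacer, on either strand of every reference
contig, with identity ≥ the threshold (default 80%) is reported.  A
vectorised sliding-window mismatch count implements the default
ungapped mode; a gapped mode (edlib infix alignment, ≤ 2 indels,
identity = `(L − edits) / L`) is available for degraded protospacers.
Identity uses the spacer length as denominator in both modes — the
conservative choice, stated openly since identity conventions vary.
Placements falling inside the query's own source array are self-hits
and removed.  Sharing matrices count, per ordered strain pair, the
query's unique spacers (exact and reverse-complement duplicates
collapsed to the lexicographically smaller strand) with at least one
qualifying placement among the partner's spacers; at threshold 1.0
this reduces to exact/reverse-complement equality.  Both directions
are emitted rather than a symmetrised count, since the two are equal
only for exact matching.

## Prophage and genic attribution

Matches are padded by 32 bp per side (clipped at contig bounds) to
buffer imprecise prophage boundaries and strand ambiguity; a padded
match counts toward every prophage region it overlaps by ≥ 1 bp, with
`questionable` and `incomplete` pooled into one class and mean
identity taken over the *unpadded* matches.  Only prophage-free
matches proceed to the subtract step (matches inside any CRISPR array
are dropped as self-hits) and then to gene intersection (features of
GFF type `gene`, strand ignored): genic if overlapping any gene, else
intergenic.  The partition is exhaustive and disjoint; a padded match
overlapping two adjacent regions counts once per region, so synthetic
panels space prophages ≥ 2× pad apart when count conservation is
asserted.  Unique-spacer and total-match tallies are both reported,
as the two differ whenever one spacer places on several related
genomes.

## Statistics

`wmw_test` returns `U = #{x_i > y_j} + ½·#{x_i = y_j}`.  For pooled
sizes ≤ 12 the two-sided p-value is exact: all `C(n1+n2, n1)`
labelings of the pooled data are enumerated and the fraction with
`|U − n1·n2/2|` at least as large as observed is reported (mid-rank
tie handling falls out of counting half-pairs per labeling).  Larger
samples use the normal approximation with tie correction and
continuity correction — numerically identical to R's `wilcox.test`
with `correct = TRUE` and to scipy's asymptotic mode, verified in the
tests.  Power is plain Monte-Carlo: 10,000 replicate draws by default,
two-sided test at α, rejection fraction returned; Monte-Carlo error at
10,000 replicates is ≈ 0.3–0.5 percentage points in the regimes used
here, well inside the ±2-point comparison band.  During development
the two headline power settings were also cross-checked against an
independent R `wilcox.test` simulation, agreeing to ≈ 0.1 point.  The
80%-power sufficiency convention is reported as a flag, never
enforced.  Array-size summaries report mean, maximum and count per
class (canonical I-E, orphan I-E, pooled I-E, II-C); empty classes are
absent rather than zero.

## The synthetic panels

The generator emulates the study-like inputs end to end: multi-contig
assemblies whose canonical arrays sit 50–300 bp downstream of an
emitted Cas-operon gene run (I-E: cas3, cse1, cse2, cas7, cas5, cas6e,
cas1, cas2; II-C: cas9, cas1, cas2 plus a planted anti-repeat),
orphan arrays on a Cas-free contig or > 500 bp from any Cas gene,
prophage regions (≥ 1 kb, labelled intact/questionable/incomplete)
that donate protospacers exactly or at a stated per-base substitution
rate, spacers shared verbatim between related strains, decoy gene
annotations, and paired 150-bp reads (fragment 2–3× read length,
substitution errors only, constant qualities) from a mixed community
with a host decoy genome built to share no 31-mer with the community.

Defaults mirror the modelled systems: 29-bp repeats, 32-bp spacers,
canonical I-E arrays of 8–25 spacers, orphan I-E arrays of 15–40
(orphans larger, as observed in the motivating clade), II-C arrays of
3–12; tetraloops default to GTTC (canonical) and TTCG (orphan) so the
two contexts are distinguishable by loop, and all sizes are plan-driven
rather than hard-coded.  Repeat and spacer length distributions are
genre-typical choices, not values estimated from any dataset.

Two generator properties make "exact recovery" a well-posed claim.
First, features are laid out sequentially with ≥ 600 bp gaps, so no
two planted features overlap and the 500-bp context rule is never
ambiguous.  Second, the genome columns immediately flanking each
repeat copy are redrawn until no base reaches the detector's 75%
agreement level (prophage-sourced and shared spacers are pinned;
free bases absorb the redraw).  Without this, a column shared by
chance across copies is *indistinguishable from repeat* to any
structure-based detector, and the planted coordinates would simply be
wrong as ground truth.  One integer seed drives a single generator in
plan order, so equal plans and seed give byte-identical files.

What the panels do **not** emulate — and hence what passing tests do
not show about real data: sequencing indels and quality-dependent
errors, phylogenetic divergence between strains (backbones are
i.i.d. random, so cross-strain homology exists only where planted),
repeat-internal mutation between array copies, assembly
fragmentation/collapse, and real tetraloop diversity.  Recall and
recovery results on the panels are therefore statements about the
algorithms' correctness under their stated contracts, not about
sensitivity on real sequencing runs.

## Problem sizes in the validation suite

The shipped suites run at deliberate desk scale: a 20-strain panel
(~64 kb per strain) for recall/typing/context, a 3-strain community at
20× *community* coverage (host pairs excluded from the coverage
budget — at 30% host contamination the naive pair count would leave
14× and occasional unspanned spacers) for read mining, 200 random
32-mers against 50 kb for the matching oracle, 100 random interval
layouts for the attribution oracle, all rank arrangements at pooled
n ≤ 10 for the exact test, and 10,000 Monte-Carlo replicates per
power estimate.

## Known limitations

- Detection assumes repeat copies are near-identical (≤ 3 edits from
  consensus by default); heavily degenerated relic arrays will be
  missed or truncated.
- The exhaustive matcher is quadratic in (spacers × reference); it is
  intended for strain panels and spacer sets, not metagenome-scale
  references.
- The read miner reports spacer content, not array order; adjacency
  information present in single reads is not assembled into longer
  array reconstructions.
- Host filtering by exact 31-mers under-removes host reads carrying
  sequencing errors; with error-bearing data, swap in a real aligner
  behind the same pair-level contract.
- `fold_hairpin` ignores thermodynamics; a stem of exact complements
  is not necessarily the minimum-free-energy structure.
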