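# Methods

## Karyotypes as partitions

The package models a karyotype as a partition of atomic units into blocks
(chromosomes). Units are ALG parts: an unfissioned ancestral linkage group
keeps its bare label (`ALG7`); an ALG observed on k ≥ 2 chromosomes is
split into parts `ALGx-1 … ALGx-k`, numbered in descending gene-support
order with ties broken by chromosome label, so output is deterministic.
The unit universe is fixed by the descendant painting; the ancestor is
expressed on that universe by grouping each ALG's parts into one block
(`refine_to_universe`).

Only two event types exist: a fission splits one block into two, a fusion
merges two blocks. Translocations, inversions and breakpoint reuse are
deliberately outside the model — the analysis is membership-based and
independent of intrachromosomal rearrangement, so those events are either
invisible (inversions) or counted as their fission+fusion decomposition. A
chromosome carrying m units counts m − 1 fusions, so a three-way fusion
such as L2 = ALG2-1 + ALG5 + ALG16 is two events; this is the only tally
consistent with the case study's printed totals (4 fusions for the
littorinid lineage).

### The closed-form count and its oracle

With m = meet(p, q) (all non-empty pairwise block intersections),
fissions = |m| − |p| and fusions = |m| − |q|. Two caveats discovered and
documented during verification:

* The count is minimal over *histories that never split a fusion product*
  (no breakpoint reuse). In an unrestricted split/merge walk, merging
  {a,b} with {c,d} and resplitting as {a,c}/{b,d} realizes a reciprocal
  translocation in two moves, where the fission/fusion model counts four.
  The BFS oracle therefore marks merge products as unsplittable; under
  that rule every history factors as fissions down to a common refinement
  followed by fusions, the best common refinement is the meet, and the
  oracle (plus an independent exhaustive search over common refinements)
  confirms equality on all 5-unit partition pairs and seeded random
  6–8-unit pairs.
* The event distance d(p, q) = fissions + fusions is symmetric (with the
  two tallies swapped) but is **not** a path metric: composing histories
  through an intermediate karyotype can re-cut fusion products and be
  cheaper than any single history. A test documents the counterexample.

## Homology calling and painting

Chromosome↔ALG (or chromosome↔chromosome) homology is called from the
ortholog contingency table. For a cell with count k, row margin n (genes
mapped on the chromosome), column margin K (genes of the ALG) and total N,
the p-value is the upper-tail hypergeometric probability P[X ≥ k]
(`scipy.stats.hypergeom.sf`), with Benjamini–Hochberg FDR over all cells
(`statsmodels`). A call is significant when q ≤ 0.05, k ≥ 10 and
k/n ≥ 0.05. The count and fraction gates suppress translocation and
mis-anchoring noise, which produces cells of a few genes scattered across
chromosomes. A 1×1 table is a forced configuration: p = 1 by convention
and the count gates decide alone. The source study called homologies by
dot-plot inspection with MCScanX blocks; this explicit test is a
reproducible formalization of that judgement, with all thresholds exposed.
The known power limitation: a small fission product fused into a large
chromosome (part size below roughly row-margin/17 plus a few counts) may
not reach significance — at 300 genes per ALG this affects parts of a few
dozen genes.

## Shared events and MRCA reconstruction

Per-lineage event sets are read directly off the painting: one fission per
ALG on > 1 chromosome, one fusion per multi-unit chromosome. A fission is
shared between lineages when the same ALG fissions in both and — when gene
memberships are available — its products match one-to-one with gene-content
Jaccard ≥ 0.5 (the breakpoints agree within the single-copy ortholog set;
this makes the breakpoint-coincidence assumption testable on real data). A
fusion is shared for every maximal unit set of size ≥ 2 co-resident in
both lineages; a shared subset of a larger fusion counts once as shared,
leaving the remainder as a lineage-specific completion ({ALG5, ALG16}
inside L2's three-way fusion is one shared plus one littorinid-specific
fusion).

The MRCA is constructed by applying only the shared events to the root,
then certified: exhaustively against every candidate partition when the
unit universe has ≤ 8 units (Bell-number enumeration), otherwise by
verifying that no single split or merge of the MRCA lowers the total
d(root, MRCA) + d(MRCA, k₁) + d(MRCA, k₂). Ties found by the exhaustive
search are reported in the certificate rather than broken silently. ALGs
absent from a lineage's painting are warned about and dropped from that
comparison's universe, never imputed.

`classify_inheritance` labels a chromosome *direct* exactly when its
composition is a single bare-ALG unit — no fission or fusion anywhere in
its history — and *derived* otherwise (a lone fission product is derived).

## The synthetic-data generator

The simulator evolves genomes from an n_alg-chromosome ancestor along a
three-taxon tree ((tip_a, tip_b), reference): a shared branch to the
ingroup ancestor, then one branch per tip, each carrying scripted or random
events. Defaults mirror the study conditions: 17 ALGs, 300 genes per ALG,
1 % per-gene translocation (observed placement moved to a uniformly random
other chromosome, emulating the ~8 % unanchored-scaffold leakage and
mis-anchoring of real assemblies), 2 % gene loss (single-copy-filter
attrition). Every run is deterministic given its seed.

Design choices that matter for interpreting test results:

* **Fission breakpoints** are uniform over interior points that leave both
  products ≥ min_genes (10) genes, and only blocks with ≥ 2·min_genes are
  eligible. Unboundedly small products would be invisible to the painter's
  own count gate by construction, making "recovery" ill-posed rather than
  informative.
* **Random-regime identifiability** (`alg_reuse="tree"`, the default): at
  most one event touches any ALG anywhere in the tree, and a fusion never
  joins two parts of the same ALG. Without this, three configurations are
  unrecoverable in principle or in power at membership granularity: sister
  fission products re-fused (a no-op to painting), a small shared-fission
  product fused into a large chromosome (test power), and independent
  same-ALG fissions on both tips (aliasing as shared). `alg_reuse="branch"`
  relaxes the exclusion to within-branch for users who want the harder,
  partially unidentifiable regime.
* Gene order within chromosomes is emitted with uniform spacing but
  shuffled, so nothing downstream can accidentally exploit collinearity.
* Event type is fission or fusion with probability 0.5 each, subject to
  availability; per-branch event counts default to uniform 1–4.

What the generator does **not** emulate: sequence evolution, real gene
length/spacing distributions, collinear block structure, segmental
duplication, assembly chimerism beyond uniform translocation, or lineage
rate variation. Passing recovery tests therefore shows the inference is
correct at membership granularity under calibrated noise — not that real
assemblies meet those noise levels.

## The packaged case study

`karyoevol.fixtures` encodes the littorinid and scallop karyotypes and
event scripts from published chromosome-homology maps (data files under
`src/karyoevol/data/`, regenerated byte-identically by
`write_case_files`). Cross-lineage part identities honor the published
dot-plot homologies (PY19 carries ALG2-1, the part fused into L2; PY13
carries ALG2-2; PY9 carries ALG4-1; PY1 keeps ALG10 intact). Chromosome
numbers the sources leave unassigned are filled in ascending ALG order and
are presentation only. Synthetic paintings attach nominal supports
(300 genes per ALG, parts split 160/140) and deterministic reference-gene
memberships consistent with a single shared breakpoint per shared fission;
they are synthetic stand-ins for paintings of the sequenced genomes, which
the package never needs.

## Problem sizes and numerical notes

Test-suite simulations use 17 ALGs × 300 genes (the study scale) with 100
replicates for event recovery, and 60-gene ALGs for small certified
instances; oracle equivalence is exhaustive over all 5-unit partition
pairs (Bell(5)² = 2704) plus 200 random 6–8-unit pairs; hypergeometric
p-values are checked against draw enumeration for every reachable
(N, K, n, k) with N ≤ 12 (1815 configurations). All randomness flows from
explicit integer seeds through `numpy.random.default_rng`. p-values are
compared exactly (to 1e-12) against enumeration; no tolerance is applied
to event counts, which are integers throughout.

## Known limitations

* Homology calls are membership-based; collinearity or synteny-block
  evidence is out of scope by design, so a chromosome pair sharing many
  orthologs through ancient segmental shuffling would still be called
  homologous.
* Shared-fusion matching has no gene-level mode (co-residency is already a
  strong signal), so independent identical fusions in two lineages alias
  as shared.
* The MRCA optimality certificate is local (single-move) on universes
  above 8 units; exhaustive certification of the 21-unit case study is
  combinatorially out of reach, though the local certificate passes and
  small simulated instances certify exhaustively.
* With more than two ingroup lineages the reconstruction would be a
  general small-parsimony problem, which is out of scope.
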