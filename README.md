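# karyoevol

Chromosome painting and fission/fusion parsimony for karyotype evolution.

Bilaterian genomes descend from an ancestor with 17 chromosomes — the ancient
linkage groups (ALGs) — whose gene content is still recognizable in many
extant genomes after 500+ million years. Given gene-position tables and
single-copy ortholog pairs, `karyoevol` paints each extant chromosome as a
composition of ALG parts, counts the chromosomal fissions and fusions that
separate a karyotype from its ancestor, detects events shared between
lineages, and reconstructs the most parsimonious karyotype of their most
recent common ancestor. It was built around the comparison of littorinid
marine snails (*n* = 17) with the scallop *Patinopecten yessoensis*
(*n* = 19), and ships that case study as a packaged, regenerable fixture —
no sequencing data required.

## The model

A karyotype is a **set partition**: atomic units are ALG parts (an intact
`ALG7`, or fission products `ALG2-1`, `ALG2-2`), and each block is one
chromosome. Events are whole-block **fissions** (split a block in two) and
**fusions** (merge two blocks); translocations and breakpoint reuse are
outside the model, matching an analysis that is independent of
intrachromosomal rearrangements. For an ancestor *p* and descendant *q* on
the same unit universe, with *m* their coarsest common refinement (meet),
the minimal event counts are closed-form:

    fissions = |m| − |p|        fusions = |m| − |q|

so the chromosome-number identity |q| = |p| + fissions − fusions always
holds. Minimality is not assumed: an exhaustive breadth-first search over
event histories (and an independent search over common refinements)
verifies it in the test suite.

Chromosome↔ALG homology is decided statistically: each cell of the
chromosome × ALG ortholog contingency table gets an upper-tail
hypergeometric p-value, Benjamini–Hochberg FDR control across cells, and
absolute-count (≥ 10 genes) and fraction (≥ 5 % of the chromosome's mapped
genes) gates against translocation/misassembly noise.

Shared events between two lineages are matched at ALG granularity (with
optional gene-level breakpoint confirmation by Jaccard overlap of fission
products); applying only the shared events to the root yields the MRCA
karyotype, certified optimal exhaustively on small unit universes and by
local-move checks on large ones.

A seeded genome-evolution simulator emits gene BEDs, ortholog TSVs, an ALG
assignment table, a Newick tree and full ground truth, so the entire
pipeline is testable offline.

## Worked example

```sh
python examples/03_reconstruct_mrca.py
```

prints (abridged):

```
MRCA karyotype: 19 chromosomes
  block-identical to the scallop karyotype: True
shared events: 3 fissions (ALG13, ALG2, ALG4), 1 fusion (ALG16+ALG5)
littorinid-specific: 1 fissions, 3 fusions
scallop-specific: 0 fissions, 0 fusions
total events: 8  (certificate: local, optimal=True)
littorinid chromosomes: 9 directly inherit one intact ALG, 8 are fission/fusion products
```

Reading: three ALG fissions and the ALG5+ALG16 fusion are present in both
lineages, so parsimony places them before the bivalve–gastropod split — the
reconstructed ancestor already had the scallop's 19-chromosome karyotype.
The littorinid lineage then fissioned ALG10 and made three more fusions,
returning to 17 chromosomes (17 + 4 − 4). `examples/01_paint_a_genome.py`
shows painting from raw ortholog tables and
`examples/02_count_fission_fusion_events.py` the closed-form event count.

The same stages are available as a thin CLI:

```sh
karyoevol simulate --seed 11 --script case_study --out ds/
karyoevol paint --genes ds/littorinid.genes.bed --genome-id littorinid \
    --alg-table ds/alg_assignments.tsv \
    --orthologs ds/orthologs.littorinid--alg_ref.tsv --out paint_lit/
karyoevol reconstruct --painting littorinid paint_lit/painting.tsv \
    --painting scallop paint_sca/painting.tsv --tree ds/tree.nwk --out rec/
```

## Layout

- `src/karyoevol/karyotype.py` — partition algebra, event counts, oracles
- `src/karyoevol/synteny.py` — contingency tables, homology tests, painting, dot plots
- `src/karyoevol/inference.py` — event extraction, shared-event matching, MRCA reconstruction
- `src/karyoevol/simulate.py` — seeded genome-evolution simulator with ground truth
- `src/karyoevol/fixtures.py` + `src/karyoevol/data/` — the packaged case study
- `src/karyoevol/io_formats.py`, `src/karyoevol/cli.py` — formats and the CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
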