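"""Paint a synthetic genome's chromosomes in ancestral-linkage-group coordinates.

Simulates two genomes descended from the 17-ALG bilaterian ancestor along the
littorinid/scallop event scripts, then paints the littorinid-like genome from
its single-copy ortholog table against the ALG reference.
"""

from karyoevol import fixtures
from karyoevol.synteny import paint_genome

sim = fixtures.simulate_case(seed=11)
painting = paint_genome(
    sim.gene_records["littorinid"],
    sim.alg_table,
    sim.ortholog_pairs[("littorinid", "alg_ref")],
)

print(f"{len(painting.composition)} chromosomes painted\n")
for chrom in sorted(painting.composition):
    units = painting.composition[chrom]
    parts = ", ".join(f"{u} ({painting.support[u]} genes)" for u in units)
    print(f"  {chrom:>5}: {parts}")

print(
    "\nEach line is one chromosome and its ALG composition: a bare label"
    "\n(ALG7) is an intact ancestral chromosome, a suffixed label (ALG2-1)"
    "\nis one product of an ALG fission; several labels on one line mean the"
    "\nchromosome is a fusion product. Gene counts are the supporting"
    "\nsingle-copy orthologs."
)
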