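"""Count fission/fusion events between the bilaterian ancestor and each lineage.

Uses the packaged case study: the littorinid (n = 17) and scallop
P. yessoensis (n = 19) karyotypes encoded from published chromosome-homology
maps. The minimal event count has a closed form through the coarsest common
refinement (meet) of the two partitions.
"""

from karyoevol import fixtures
from karyoevol.karyotype import count_events, meet, refine_to_universe

case = fixtures.case_study()

for k in (case.littorinid, case.scallop):
    root = refine_to_universe(case.root, k.units)
    fissions, fusions = count_events(root, k)
    m = meet(root, k)
    print(
        f"{k.name:>10}: {len(k)} chromosomes; common refinement has {len(m)} blocks"
        f" -> {fissions} fissions, {fusions} fusions from the {len(case.root)}-ALG root"
    )
    assert len(k) == len(case.root) + fissions - fusions  # chromosome-number identity

print(
    "\nThe littorinid karyotype keeps 17 chromosomes because its 4 fissions"
    "\nare balanced by 4 fusions; the scallop's 3 fissions and 1 fusion give"
    "\n17 + 3 - 1 = 19."
)
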