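"""The littorinid / scallop karyotype case study, encoded from published maps.

Littorinid snails (*Littorina brevicula*, *Littoraria sinensis*; n = 17) and
the scallop *Patinopecten yessoensis* (n = 19) both descend from a bilaterian
ancestor with 17 ancestral linkage groups (ALGs).  The published
chromosome-homology maps pin down both lineages' event scripts:

scallop (PY):
    fissions  ALG13 -> PY5 + PY16, ALG4 -> PY9 + PY17, ALG2 -> PY13 + PY19
    fusion    ALG5 + ALG16 -> PY2

littorinid (L):
    fissions  ALG2, ALG4, ALG13 (-> L5 + L8), ALG10 (-> L13 + L15)
    fusions   ALG2-1 + ALG5 + ALG16 -> L2, ALG2-2 + ALG11 -> L3,
              ALG4-1 + ALG12 -> L1

Cross-lineage part identities follow the dot-plot homology map (PY8 + PY9
<-> L1, PY2 + PY19 <-> L2, PY11 + PY13 <-> L3, PY1 <-> L13 + L15), so e.g.
PY19 carries ALG2-1 (the part fused into L2) and PY13 carries ALG2-2.
Chromosome numbers the sources leave unassigned (intact ALGs) are filled in
ascending ALG order; these names are presentation only.

The module also builds *synthetic* paintings for both lineages — nominal
gene supports and deterministic reference-gene memberships consistent with a
single shared breakpoint per shared fission — so that gene-level machinery
can run on the case study without the sequenced genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .io_formats import read_eventset, read_karyotype, write_report
from .karyotype import (
    EventSet,
    FissionEvent,
    FusionEvent,
    KaryotypePartition,
    apply_events,
    root_partition,
)
from .simulate import SimResult, SimulationConfig, simulate
from .synteny import Painting, _alg_sort_key

__all__ = [
    "CaseStudy",
    "alg_root",
    "littorinid_event_script",
    "scallop_event_script",
    "shared_event_script",
    "littorinid_specific_script",
    "littorinid_karyotype",
    "scallop_karyotype",
    "littorinid_painting",
    "scallop_painting",
    "case_study",
    "simulate_case",
    "write_case_files",
    "load_packaged_case",
]

GENES_PER_ALG = 300
#: shared fission breakpoints: genes 1..160 go to part -1, the rest to part -2
PART1_GENES = 160

_LITTORINID_FISSIONS = ("ALG2", "ALG4", "ALG13", "ALG10")
_SCALLOP_FISSIONS = ("ALG13", "ALG4", "ALG2")

_SCALLOP_HOMES = {
    "ALG13-1": "PY5", "ALG13-2": "PY16",
    "ALG4-1": "PY9", "ALG4-2": "PY17",
    "ALG2-2": "PY13", "ALG2-1": "PY19",
    "ALG10": "PY1", "ALG12": "PY8", "ALG11": "PY11",
}
_SCALLOP_SPARE = ["PY3", "PY4", "PY6", "PY7", "PY10", "PY12", "PY14", "PY15", "PY18"]

_LITTORINID_HOMES = {
    "ALG13-1": "L5", "ALG13-2": "L8",
    "ALG10-1": "L13", "ALG10-2": "L15",
}
_LITTORINID_SPARE = ["L4", "L6", "L7", "L9", "L10", "L11", "L12", "L14", "L16", "L17"]


def alg_root() -> KaryotypePartition:
    return root_partition(17)


def littorinid_event_script() -> EventSet:
    return EventSet(
        branch=("ALG-root", "littorinid"),
        fissions=tuple(
            FissionEvent(alg=a, products=(f"{a}-1", f"{a}-2")) for a in _LITTORINID_FISSIONS
        ),
        fusions=(
            FusionEvent(members=frozenset({"ALG2-1", "ALG5", "ALG16"}), chromosome="L2"),
            FusionEvent(members=frozenset({"ALG2-2", "ALG11"}), chromosome="L3"),
            FusionEvent(members=frozenset({"ALG4-1", "ALG12"}), chromosome="L1"),
        ),
    )


def scallop_event_script() -> EventSet:
    return EventSet(
        branch=("ALG-root", "scallop"),
        fissions=tuple(
            FissionEvent(alg=a, products=(f"{a}-1", f"{a}-2")) for a in _SCALLOP_FISSIONS
        ),
        fusions=(
            FusionEvent(members=frozenset({"ALG5", "ALG16"}), chromosome="PY2"),
        ),
    )


def shared_event_script() -> EventSet:
    """Events common to both lineages (they predate the bivalve-gastropod split)."""
    return EventSet(
        branch=("ALG-root", "mrca"),
        fissions=tuple(
            FissionEvent(alg=a, products=(f"{a}-1", f"{a}-2")) for a in ("ALG2", "ALG4", "ALG13")
        ),
        fusions=(FusionEvent(members=frozenset({"ALG5", "ALG16"}), chromosome="PY2"),),
    )


def littorinid_specific_script() -> EventSet:
    return EventSet(
        branch=("mrca", "littorinid"),
        fissions=(FissionEvent(alg="ALG10", products=("ALG10-1", "ALG10-2")),),
        fusions=(
            FusionEvent(members=frozenset({"ALG2-1", "ALG5", "ALG16"}), chromosome="L2", tally=1),
            FusionEvent(members=frozenset({"ALG2-2", "ALG11"}), chromosome="L3"),
            FusionEvent(members=frozenset({"ALG4-1", "ALG12"}), chromosome="L1"),
        ),
    )


def _with_homes(k: KaryotypePartition, homes: dict[str, str], spare: list[str],
                name: str) -> KaryotypePartition:
    """Name chromosomes: explicit homes first, spare labels in ALG order."""
    renames: dict[str, str] = {}
    leftovers = []
    for chrom, units in k.blocks.items():
        if len(units) == 1:
            (unit,) = units
            if unit in homes:
                renames[chrom] = homes[unit]
            else:
                leftovers.append((unit, chrom))
        # multi-unit blocks already carry their fusion chromosome name
    leftovers.sort(key=lambda t: _alg_sort_key(t[0]))
    for label, (_unit, chrom) in zip(spare, leftovers):
        renames[chrom] = label
    return k.rename(renames, name=name)


def littorinid_karyotype() -> KaryotypePartition:
    k = apply_events(alg_root(), littorinid_event_script(), name="littorinid")
    return _with_homes(k, _LITTORINID_HOMES, _LITTORINID_SPARE, "littorinid")


def scallop_karyotype() -> KaryotypePartition:
    k = apply_events(alg_root(), scallop_event_script(), name="scallop")
    return _with_homes(k, _SCALLOP_HOMES, _SCALLOP_SPARE, "scallop")


def _ref_genes(alg: str) -> list[str]:
    return [f"{alg}_g{i + 1:04d}" for i in range(GENES_PER_ALG)]


def _painting_from_karyotype(k: KaryotypePartition, genome_id: str) -> Painting:
    """Synthetic painting: nominal supports and shared-breakpoint memberships."""
    composition: dict[str, list[str]] = {}
    support: dict[str, int] = {}
    members: dict[str, frozenset[str]] = {}
    for chrom, units in k.blocks.items():
        ordered = sorted(units, key=_alg_sort_key)
        composition[chrom] = ordered
        for unit in ordered:
            alg = unit.split("-")[0]
            genes = _ref_genes(alg)
            if unit == alg:
                sel = genes
            elif unit.endswith("-1"):
                sel = genes[:PART1_GENES]
            else:
                sel = genes[PART1_GENES:]
            support[unit] = len(sel)
            members[unit] = frozenset(sel)
    return Painting(genome_id, composition, support, members)


def littorinid_painting() -> Painting:
    return _painting_from_karyotype(littorinid_karyotype(), "littorinid")


def scallop_painting() -> Painting:
    return _painting_from_karyotype(scallop_karyotype(), "scallop")


@dataclass
class CaseStudy:
    root: KaryotypePartition
    littorinid_events: EventSet
    scallop_events: EventSet
    littorinid: KaryotypePartition
    scallop: KaryotypePartition
    littorinid_paint: Painting
    scallop_paint: Painting
    newick: str = "((littorinid,scallop),alg_ref);"


def case_study() -> CaseStudy:
    return CaseStudy(
        root=alg_root(),
        littorinid_events=littorinid_event_script(),
        scallop_events=scallop_event_script(),
        littorinid=littorinid_karyotype(),
        scallop=scallop_karyotype(),
        littorinid_paint=littorinid_painting(),
        scallop_paint=scallop_painting(),
    )


def simulate_case(
    seed: int,
    genes_per_alg: int = GENES_PER_ALG,
    translocation_rate: float = 0.01,
    gene_loss_rate: float = 0.02,
) -> SimResult:
    """Full synthetic genomes evolved along the case study's event scripts.

    Scripted fissions carry the fixture's breakpoint (genes 1..160 of 300 to
    part -1, scaled to ``genes_per_alg``), so both lineages share breakpoints
    by construction and every part is large enough to paint.
    """

    def _sized(e: EventSet) -> EventSet:
        n1 = round(genes_per_alg * PART1_GENES / GENES_PER_ALG)
        return EventSet(
            branch=e.branch,
            fissions=tuple(
                FissionEvent(
                    alg=f.alg,
                    products=f.products,
                    support={f.products[0]: n1, f.products[1]: genes_per_alg - n1},
                )
                for f in e.fissions
            ),
            fusions=e.fusions,
        )

    shared = _sized(shared_event_script())
    lit = _sized(littorinid_specific_script())
    # scallop branch: no further events
    scal = EventSet(branch=("mrca", "scallop"))
    naming = {
        "littorinid": {frozenset(b): c for c, b in littorinid_karyotype().blocks.items()},
        "scallop": {frozenset(b): c for c, b in scallop_karyotype().blocks.items()},
    }
    cfg = SimulationConfig(
        seed=seed,
        n_alg=17,
        genes_per_alg=genes_per_alg,
        tips=("littorinid", "scallop"),
        events_per_branch={"shared": shared, "littorinid": lit, "scallop": scal},
        translocation_rate=translocation_rate,
        gene_loss_rate=gene_loss_rate,
        chromosome_names=naming,
    )
    return simulate(cfg)


# ---------------------------------------------------------------------------
# Packaged data files (regenerable)
# ---------------------------------------------------------------------------

_FILES = {
    "alg_root.tsv": lambda: alg_root(),
    "littorinid_karyotype.tsv": littorinid_karyotype,
    "scallop_karyotype.tsv": scallop_karyotype,
    "littorinid_events.json": littorinid_event_script,
    "scallop_events.json": scallop_event_script,
}


def write_case_files(outdir: str | Path) -> list[Path]:
    """Regenerate the packaged case-study data files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for fname, builder in _FILES.items():
        fmt = "json" if fname.endswith(".json") else "tsv"
        written.append(write_report(builder(), outdir / fname, format=fmt))
    return written


def load_packaged_case() -> CaseStudy:
    """Load the case study from the data files shipped with the package."""
    data = resources.files("karyoevol") / "data"
    with resources.as_file(data) as d:
        root = read_karyotype(d / "alg_root.tsv", "ALG-root")
        lit_k = read_karyotype(d / "littorinid_karyotype.tsv", "littorinid")
        sca_k = read_karyotype(d / "scallop_karyotype.tsv", "scallop")
        lit_e = read_eventset(d / "littorinid_events.json")
        sca_e = read_eventset(d / "scallop_events.json")
    return CaseStudy(
        root=root,
        littorinid_events=lit_e,
        scallop_events=sca_e,
        littorinid=lit_k,
        scallop=sca_k,
        littorinid_paint=_painting_from_karyotype(lit_k, "littorinid"),
        scallop_paint=_painting_from_karyotype(sca_k, "scallop"),
    )
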