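"""Synthetic genome evolution from a configurable ancestral karyotype.

Genomes descend from an ancestor of ``n_alg`` chromosomes (the ALGs) along a
3-taxon tree ``((tip_a, tip_b), reference)``: a shared branch from the root
to the ingroup ancestor, then one branch per tip.  Each branch carries
scripted or random fission/fusion events.  Fissions split an intact ALG's
gene list at a random interior point (both products keep at least
``min_genes`` genes, so a real fission is never invisible to the painter's
count gate by construction); fusions merge two chromosomes.  Per-gene
translocation (uniform reassignment to another chromosome, emulating
assembly/anchoring noise) and gene loss (single-copy-filter attrition) are
then applied independently per genome.  Everything is deterministic given
the seed, and the emitted tables are exactly the formats the ingestion layer
reads, with full ground truth alongside.

Gene order within chromosomes is emitted with uniform spacing but shuffled,
so nothing downstream can accidentally depend on collinearity: the analysis
is membership-based by design.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .io_formats import ALGAssignment, GeneRecord, OrthologPair
from .karyotype import EventSet, FissionEvent, FusionEvent, KaryotypePartition, alg_of
from .synteny import Painting

__all__ = ["SimulationConfig", "SimTruth", "SimResult", "simulate", "write_dataset"]

REFERENCE_GENOME = "alg_ref"


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    ``events_per_branch`` maps branch names (``"shared"``, tip names) to a
    scripted :class:`EventSet`, an integer number of random events, or None
    for a random count of 1-4.  Rates are per gene per genome.
    """

    seed: int
    n_alg: int = 17
    genes_per_alg: int = 300
    tips: tuple[str, str] = ("tip_a", "tip_b")
    events_per_branch: Mapping[str, object] | None = None
    translocation_rate: float = 0.01
    gene_loss_rate: float = 0.02
    min_genes: int = 10
    fission_prob: float = 0.5
    #: "tree": an ALG is touched by at most one event anywhere in the tree
    #: (keeps random histories identifiable from membership painting);
    #: "branch": exclusion applies within each branch only.
    alg_reuse: str = "tree"
    #: per-tip chromosome naming: {tip: {frozenset(units): chromosome name}};
    #: blocks without an entry keep their construction name.
    chromosome_names: Mapping[str, Mapping[frozenset, str]] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for every stochastic run")
        for rate in (self.translocation_rate, self.gene_loss_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"rate {rate} outside [0, 1)")
        if self.genes_per_alg < 1:
            raise ValueError("genes_per_alg must be >= 1")
        if self.n_alg < 1:
            raise ValueError("n_alg must be >= 1")
        if self.alg_reuse not in ("tree", "branch"):
            raise ValueError(f"alg_reuse must be 'tree' or 'branch', got {self.alg_reuse!r}")

    @property
    def newick(self) -> str:
        return f"(({self.tips[0]},{self.tips[1]}),{REFERENCE_GENOME});"


@dataclass
class SimTruth:
    """Ground truth emitted with every simulated dataset."""

    branch_events: dict[str, EventSet]
    paintings: dict[str, Painting]
    #: tip gene id -> (true chromosome, observed chromosome, ALG, reference gene)
    assignments: dict[str, dict[str, tuple[str, str, str, str]]]
    root: KaryotypePartition

    def pair_tally(self, genome_a: str, genome_b: str) -> dict[tuple[str, str], int]:
        """Independent chromosome-pair ortholog tally from the raw assignments.

        Counts observed-chromosome co-occurrences of genes surviving in both
        genomes by direct dictionary accumulation (an oracle for the
        contingency builder).
        """
        by_ref_a = {v[3]: v[1] for v in self.assignments[genome_a].values()}
        if genome_b == REFERENCE_GENOME:
            # reference chromosomes are the ALGs themselves
            by_ref_b = {ref: ref.split("_g")[0] for ref in by_ref_a}
        else:
            by_ref_b = {v[3]: v[1] for v in self.assignments[genome_b].values()}
        tally: dict[tuple[str, str], int] = {}
        for ref, ca in by_ref_a.items():
            cb = by_ref_b.get(ref)
            if cb is None:
                continue
            tally[(ca, cb)] = tally.get((ca, cb), 0) + 1
        return tally


@dataclass
class SimResult:
    config: SimulationConfig
    gene_records: dict[str, list[GeneRecord]]
    ortholog_pairs: dict[tuple[str, str], list[OrthologPair]]
    alg_table: list[ALGAssignment]
    truth: SimTruth


class _GenomeState:
    """Blocks (chromosomes) of ordered unit gene lists during simulation."""

    def __init__(self, blocks: dict[str, list[str]], unit_genes: dict[str, list[str]]):
        self.blocks = {c: list(us) for c, us in blocks.items()}
        self.unit_genes = {u: list(g) for u, g in unit_genes.items()}

    def copy(self) -> "_GenomeState":
        return _GenomeState(self.blocks, self.unit_genes)

    def block_genes(self, chrom: str) -> int:
        return sum(len(self.unit_genes[u]) for u in self.blocks[chrom])

    def to_partition(self, name: str) -> KaryotypePartition:
        return KaryotypePartition(name, {c: frozenset(us) for c, us in self.blocks.items()})


def _apply_fission(state: _GenomeState, event: FissionEvent, rng, min_genes: int) -> None:
    home = next((c for c, us in state.blocks.items() if event.alg in us), None)
    if home is None:
        raise ValueError(f"fission of {event.alg!r}: not an intact unit of the current karyotype")
    if state.blocks[home] != [event.alg]:
        raise ValueError(f"fission of {event.alg!r}: chromosome {home!r} is fused")
    genes = state.unit_genes.pop(event.alg)
    if len(genes) < 2 * min_genes:
        raise ValueError(f"fission of {event.alg!r}: only {len(genes)} genes (< 2*min_genes)")
    if event.support:
        sizes = [event.support[p] for p in event.products]
        if sum(sizes) != len(genes):
            raise ValueError(f"fission of {event.alg!r}: scripted sizes do not sum to gene count")
        cuts = np.cumsum(sizes)[:-1]
    else:
        cuts = [int(rng.integers(min_genes, len(genes) - min_genes + 1))]
        if len(event.products) != 2:
            raise ValueError("random-regime fissions are two-part")
    del state.blocks[home]
    lo = 0
    for prod, hi in zip(event.products, list(cuts) + [len(genes)]):
        state.unit_genes[prod] = genes[lo:hi]
        state.blocks[prod] = [prod]
        lo = hi


def _apply_fusion(state: _GenomeState, event: FusionEvent) -> None:
    homes: list[str] = []
    for member in sorted(event.members):
        found = [c for c, us in state.blocks.items() if member in us]
        if not found:
            raise ValueError(f"fusion into {event.chromosome!r}: unit {member!r} absent")
        homes.append(found[0])
    distinct = list(dict.fromkeys(homes))
    if len(distinct) < 2:
        raise ValueError(
            f"fusion into {event.chromosome!r}: cannot fuse a chromosome with itself"
        )
    merged: list[str] = []
    for c in distinct:
        merged.extend(state.blocks.pop(c))
    state.blocks[event.chromosome] = merged


def _random_events(
    state: _GenomeState,
    branch: tuple[str, str],
    n_events: int,
    rng,
    cfg: SimulationConfig,
    touched: set[str],
) -> EventSet:
    """Sample and apply random events; no ALG in ``touched`` is reused.

    ``touched`` is per-branch or tree-wide depending on ``cfg.alg_reuse``.
    Fusions never join two parts of the same ALG: such a merge would undo a
    fission invisibly at membership granularity, leaving the ground truth
    unrecoverable by construction.
    """
    import itertools as _it

    fissions: list[FissionEvent] = []
    fusions: list[FusionEvent] = []
    for _ in range(n_events):
        fission_ok = [
            c
            for c, us in state.blocks.items()
            if len(us) == 1 and us[0] == alg_of(us[0]) and us[0] not in touched
            and len(state.unit_genes[us[0]]) >= 2 * cfg.min_genes
        ]
        fusion_blocks = [
            c
            for c, us in state.blocks.items()
            if not ({alg_of(u) for u in us} & touched)
        ]
        fusion_pairs = [
            (c1, c2)
            for c1, c2 in _it.combinations(sorted(fusion_blocks), 2)
            if not (
                {alg_of(u) for u in state.blocks[c1]}
                & {alg_of(u) for u in state.blocks[c2]}
            )
        ]
        do_fission = rng.random() < cfg.fission_prob
        if do_fission and not fission_ok:
            do_fission = False
        if not do_fission and not fusion_pairs:
            do_fission = bool(fission_ok)
            if not do_fission:
                break
        if do_fission:
            chrom = fission_ok[int(rng.integers(len(fission_ok)))]
            alg = state.blocks[chrom][0]
            ev = FissionEvent(alg=alg, products=(f"{alg}-1", f"{alg}-2"))
            _apply_fission(state, ev, rng, cfg.min_genes)
            ev = FissionEvent(
                alg=alg,
                products=ev.products,
                support={p: len(state.unit_genes[p]) for p in ev.products},
                member_genes={p: frozenset(state.unit_genes[p]) for p in ev.products},
            )
            fissions.append(ev)
            touched.add(alg)
        else:
            c1, c2 = fusion_pairs[int(rng.integers(len(fusion_pairs)))]
            members = frozenset(state.blocks[c1]) | frozenset(state.blocks[c2])
            name = "+".join(sorted(members))
            n_blocks = 2
            fusions.append(FusionEvent(members=members, chromosome=name,
                                       tally=n_blocks - 1))
            _apply_fusion(state, FusionEvent(members=members, chromosome=name))
            touched |= {alg_of(u) for u in members}
    return EventSet(branch=branch, fissions=tuple(fissions), fusions=tuple(fusions))


def _scripted_events(state: _GenomeState, events: EventSet, rng, cfg: SimulationConfig) -> EventSet:
    recorded_f = []
    for ev in events.fissions:
        _apply_fission(state, ev, rng, cfg.min_genes)
        recorded_f.append(
            FissionEvent(
                alg=ev.alg,
                products=ev.products,
                support={p: len(state.unit_genes[p]) for p in ev.products},
                member_genes={p: frozenset(state.unit_genes[p]) for p in ev.products},
            )
        )
    for ev in events.fusions:
        _apply_fusion(state, ev)
    return EventSet(branch=events.branch, fissions=tuple(recorded_f), fusions=events.fusions)


def _true_painting(
    genome: str,
    state: _GenomeState,
    survivors: set[str],
) -> Painting:
    """True painting of surviving genes, with the painter's part-naming rule."""
    per_alg: dict[str, list[tuple[str, str, list[str]]]] = {}
    for chrom, units in state.blocks.items():
        for unit in units:
            genes = [g for g in state.unit_genes[unit] if g in survivors]
            if genes:
                per_alg.setdefault(alg_of(unit), []).append((chrom, unit, genes))
    composition: dict[str, list[str]] = {c: [] for c in state.blocks}
    support: dict[str, int] = {}
    members: dict[str, frozenset[str]] = {}
    for alg, incid in per_alg.items():
        incid.sort(key=lambda t: (-len(t[2]), t[0]))
        multi = len(incid) > 1
        for i, (chrom, _unit, genes) in enumerate(incid, start=1):
            label = f"{alg}-{i}" if multi else alg
            composition[chrom].append(label)
            support[label] = len(genes)
            members[label] = frozenset(genes)
    from .synteny import _alg_sort_key

    for chrom in composition:
        composition[chrom].sort(key=_alg_sort_key)
    flagged = sorted(c for c, us in composition.items() if not us)
    return Painting(genome, composition, support, members, flagged)


def simulate(config: SimulationConfig) -> SimResult:
    """Run one simulation; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    algs = [f"ALG{i + 1}" for i in range(config.n_alg)]
    ref_genes = {alg: [f"{alg}_g{i + 1:04d}" for i in range(config.genes_per_alg)] for alg in algs}
    root_state = _GenomeState({a: [a] for a in algs}, ref_genes)
    root = root_state.to_partition("ALG-root")

    scripts = dict(config.events_per_branch or {})
    branch_events: dict[str, EventSet] = {}
    tree_touched: set[str] = set()

    def run_branch(state: _GenomeState, key: str, parent: str, child: str) -> _GenomeState:
        state = state.copy()
        script = scripts.get(key)
        if isinstance(script, EventSet):
            branch_events[key] = _scripted_events(state, script, rng, config)
        else:
            n = int(script) if script is not None else int(rng.integers(1, 5))
            touched = tree_touched if config.alg_reuse == "tree" else set()
            branch_events[key] = _random_events(state, (parent, child), n, rng, config, touched)
        return state

    tip_a, tip_b = config.tips
    mrca_state = run_branch(root_state, "shared", "ALG-root", "mrca")
    tip_states = {
        tip_a: run_branch(mrca_state, tip_a, "mrca", tip_a),
        tip_b: run_branch(mrca_state, tip_b, "mrca", tip_b),
    }

    if config.chromosome_names:
        for tip, naming in config.chromosome_names.items():
            state = tip_states[tip]
            renamed = {}
            for chrom, units in state.blocks.items():
                renamed[naming.get(frozenset(units), chrom)] = units
            state.blocks = renamed

    # per-genome noise: loss, then translocation of observed placement
    gene_records: dict[str, list[GeneRecord]] = {}
    assignments: dict[str, dict[str, tuple[str, str, str, str]]] = {}
    paintings: dict[str, Painting] = {}
    tip_ids: dict[str, dict[str, str]] = {}  # genome -> ref gene -> tip gene id

    for genome, state in tip_states.items():
        all_ref = [(chrom, unit, g) for chrom, units in sorted(state.blocks.items())
                   for unit in units for g in state.unit_genes[unit]]
        keep = rng.random(len(all_ref)) >= config.gene_loss_rate
        surviving = [t for t, k in zip(all_ref, keep) if k]
        chroms = sorted(state.blocks)
        # opaque tip gene ids in shuffled order
        order = rng.permutation(len(surviving))
        ids = {}
        for rank, idx in enumerate(order):
            ids[surviving[idx][2]] = f"{genome}_g{rank + 1:05d}"
        tip_ids[genome] = ids
        translocate = rng.random(len(surviving)) < config.translocation_rate
        per_chrom: dict[str, list[tuple[str, str]]] = {c: [] for c in chroms}
        gmap: dict[str, tuple[str, str, str, str]] = {}
        for (true_chrom, unit, ref), move in zip(surviving, translocate):
            obs = true_chrom
            if move and len(chroms) > 1:
                others = [c for c in chroms if c != true_chrom]
                obs = others[int(rng.integers(len(others)))]
            gid = ids[ref]
            per_chrom[obs].append((gid, ref))
            gmap[gid] = (true_chrom, obs, alg_of(unit), ref)
        records = []
        for chrom in chroms:
            entries = per_chrom[chrom]
            shuffle = rng.permutation(len(entries))
            for pos, j in enumerate(shuffle):
                gid, _ref = entries[j]
                start = pos * 1000
                records.append(GeneRecord(genome, chrom, start, start + 500, gid))
        gene_records[genome] = records
        assignments[genome] = gmap
        paintings[genome] = _true_painting(genome, state, {ref for _, _, ref in surviving})

    # reference genome tables (complete, noise-free: it is the coordinate system)
    ref_records = []
    for alg in algs:
        for i, ref in enumerate(ref_genes[alg]):
            ref_records.append(GeneRecord(REFERENCE_GENOME, alg, i * 1000, i * 1000 + 500, ref))
    gene_records[REFERENCE_GENOME] = ref_records
    alg_table = [ALGAssignment(ref, alg) for alg in algs for ref in ref_genes[alg]]

    # ortholog tables per genome pair
    ortholog_pairs: dict[tuple[str, str], list[OrthologPair]] = {}
    ref_of = {g: {v[3]: gid for gid, v in assignments[g].items()} for g in config.tips}
    for tip in config.tips:
        pairs = [
            OrthologPair(gid, ref)
            for ref, gid in sorted(ref_of[tip].items())
        ]
        ortholog_pairs[(tip, REFERENCE_GENOME)] = [OrthologPair(p.gene_a, p.gene_b) for p in pairs]
    shared_refs = sorted(set(ref_of[tip_a]) & set(ref_of[tip_b]))
    ortholog_pairs[(tip_a, tip_b)] = [
        OrthologPair(ref_of[tip_a][r], ref_of[tip_b][r]) for r in shared_refs
    ]

    truth = SimTruth(branch_events=branch_events, paintings=paintings,
                     assignments=assignments, root=root)
    return SimResult(config, gene_records, ortholog_pairs, alg_table, truth)


def write_dataset(result: SimResult, outdir: str | Path, force: bool = False) -> Path:
    """Write a simulated dataset directory: BEDs, TSVs, Newick, truth, manifest."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for genome, records in sorted(result.gene_records.items()):
        p = outdir / f"{genome}.genes.bed"
        with open(p, "w") as fh:
            for r in records:
                fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.gene_id}\n")
        written.append(p)
    for (a, b), pairs in sorted(result.ortholog_pairs.items()):
        p = outdir / f"orthologs.{a}--{b}.tsv"
        with open(p, "w") as fh:
            for pa, pb in pairs:
                fh.write(f"{pa}\t{pb}\n")
        written.append(p)
    p = outdir / "alg_assignments.tsv"
    with open(p, "w") as fh:
        for rec in result.alg_table:
            fh.write(f"{rec.gene_id}\t{rec.alg}\n")
    written.append(p)
    p = outdir / "tree.nwk"
    p.write_text(result.config.newick + "\n")
    written.append(p)

    truth_payload = {
        "schema_version": "1",
        "kind": "sim_truth",
        "branch_events": {
            k: json.loads(json.dumps(_event_json(v))) for k, v in result.truth.branch_events.items()
        },
        "paintings": {
            g: {c: list(us) for c, us in sorted(p.composition.items())}
            for g, p in result.truth.paintings.items()
        },
        "assignments": {
            g: {gid: list(v) for gid, v in sorted(a.items())}
            for g, a in result.truth.assignments.items()
        },
    }
    p = outdir / "truth.json"
    p.write_text(json.dumps(truth_payload, indent=1) + "\n")
    written.append(p)

    manifest = {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in sorted(written)
    }
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return outdir


def _event_json(e: EventSet) -> dict:
    from .io_formats import _eventset_dict

    return _eventset_dict(e)
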