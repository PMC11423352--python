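"""Per-branch event extraction, shared-event detection, MRCA reconstruction.

Given a painting of an extant genome in ALG coordinates, the events on the
branch from the ALG ancestor are read off directly: an ALG present on more
than one chromosome fissioned; a chromosome carrying more than one unit is a
fusion product.  Comparing two lineages' event sets identifies events that
are shared (and hence, under parsimony, predate the lineages' split); applying
only the shared events to the root gives the most parsimonious karyotype of
the lineages' most recent common ancestor.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .karyotype import (
    EventSet,
    FissionEvent,
    FusionEvent,
    KaryotypePartition,
    UniverseMismatchError,
    _neighbors,
    alg_of,
    apply_events,
    count_events,
    refine_to_universe,
)
from .synteny import Painting

__all__ = [
    "EventSet",
    "FissionEvent",
    "FusionEvent",
    "event_signature",
    "extract_events",
    "MatchResult",
    "match_shared_events",
    "ReconstructionResult",
    "reconstruct_mrca",
    "InheritanceReport",
    "classify_inheritance",
]


def event_signature(e: EventSet):
    """Multiset view of an event set at ALG granularity.

    Fissions become ``(ALG, tally)`` pairs and fusions
    ``(frozenset of member ALGs, tally)`` pairs, so event sets can be
    compared across lineages (whose part labels differ) or against simulator
    ground truth.
    """
    from collections import Counter

    fis = Counter((f.alg, f.tally) for f in e.fissions)
    fus = Counter((frozenset(alg_of(m) for m in f.members), f.tally) for f in e.fusions)
    return fis, fus


def extract_events(
    root: KaryotypePartition,
    painting: Painting,
    branch: tuple[str, str] | None = None,
) -> EventSet:
    """Read the fission/fusion events between ``root`` and a painted genome.

    ALGs of the root entirely absent from the painting trigger a warning
    (possible lineage-specific loss) and are excluded from the universe; the
    resulting tallies always satisfy the closed-form ``count_events`` on the
    painting's partition.
    """
    partition = painting.to_partition()
    units = partition.units
    bases = {alg_of(u) for u in units}
    root_algs = {alg_of(u) for u in root.units}
    unknown = bases - root_algs
    if unknown:
        raise ValueError(f"painting units reference ALGs absent from the root: {sorted(unknown)}")
    missing = root_algs - bases
    if missing:
        warnings.warn(
            f"ALGs absent from painting of {painting.genome_id} "
            f"(possible lineage loss): {sorted(missing)}",
            stacklevel=2,
        )

    by_alg: dict[str, list[str]] = {}
    for u in sorted(units):
        by_alg.setdefault(alg_of(u), []).append(u)
    fissions = tuple(
        FissionEvent(
            alg=alg,
            products=tuple(parts),
            support={p: painting.support.get(p, 0) for p in parts},
            member_genes=(
                {p: painting.members.get(p, frozenset()) for p in parts}
                if painting.members is not None
                else None
            ),
        )
        for alg, parts in sorted(by_alg.items())
        if len(parts) > 1
    )
    fusions = tuple(
        FusionEvent(members=frozenset(us), chromosome=chrom)
        for chrom, us in sorted(painting.composition.items())
        if len(us) > 1
    )
    branch = branch or (root.name, painting.genome_id)
    events = EventSet(branch=branch, fissions=fissions, fusions=fusions)

    # closed-form consistency check against the partition algebra
    reduced_root = KaryotypePartition(
        root.name, {c: b for c, b in root.blocks.items() if {alg_of(u) for u in b} & bases}
    )
    counts = count_events(refine_to_universe(reduced_root, units), partition)
    assert (events.n_fissions, events.n_fusions) == tuple(counts), (
        "event tallies disagree with the partition-meet counts"
    )
    return events


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def _match_products(f1: FissionEvent, f2: FissionEvent, jmin: float):
    """Best bijection between two fissions' products by gene-content Jaccard.

    Returns (map product2 -> product1, per-pair intersections) or ``None``
    when no bijection matches every product at >= jmin.
    """
    if len(f1.products) != len(f2.products):
        return None
    g1, g2 = f1.member_genes, f2.member_genes
    best = None
    for perm in itertools.permutations(f2.products):
        js = [_jaccard(g1[p1], g2[p2]) for p1, p2 in zip(f1.products, perm)]
        if all(j >= jmin for j in js):
            score = sum(js)
            if best is None or score > best[0]:
                best = (score, perm)
    if best is None:
        return None
    perm = best[1]
    mapping = {p2: p1 for p1, p2 in zip(f1.products, perm)}
    inter = {p1: g1[p1] & g2[p2] for p1, p2 in zip(f1.products, perm)}
    return mapping, inter


@dataclass
class MatchResult:
    """Shared and lineage-specific events; iterates as (shared, s1, s2)."""

    shared: EventSet
    specific_1: EventSet
    specific_2: EventSet
    #: lineage-2 unit labels -> lineage-1 canonical labels for shared products
    relabel_2: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter((self.shared, self.specific_1, self.specific_2))


def match_shared_events(
    e1: EventSet, e2: EventSet, gene_jaccard_min: float = 0.5
) -> MatchResult:
    """Split two lineages' root-to-tip event sets into shared and specific.

    A fission is shared when the same ALG fissions in both lineages and — if
    gene memberships are recorded — its products match one-to-one with
    gene-content Jaccard >= ``gene_jaccard_min`` (the breakpoints agree).  A
    fusion is shared for every maximal unit set of size >= 2 co-resident on
    one chromosome in both lineages; a shared subset of a larger fusion
    leaves the remainder as a lineage-specific completion (e.g. a shared
    {ALG5, ALG16} core inside a three-way fusion counts as one shared plus
    one specific fusion).
    """
    fis1 = {f.alg: f for f in e1.fissions}
    fis2 = {f.alg: f for f in e2.fissions}
    shared_fissions: list[FissionEvent] = []
    shared_algs: set[str] = set()
    relabel_2: dict[str, str] = {}
    for alg in sorted(set(fis1) & set(fis2)):
        f1, f2 = fis1[alg], fis2[alg]
        if f1.member_genes is not None and f2.member_genes is not None:
            matched = _match_products(f1, f2, gene_jaccard_min)
            if matched is None:
                continue
            mapping, inter = matched
            relabel_2.update(mapping)
            shared_fissions.append(
                FissionEvent(
                    alg=alg,
                    products=f1.products,
                    support={p: len(g) for p, g in inter.items()},
                    member_genes={p: frozenset(g) for p, g in inter.items()},
                )
            )
        else:
            if len(f1.products) != len(f2.products):
                continue
            relabel_2.update(dict(zip(f2.products, f1.products)))
            shared_fissions.append(FissionEvent(alg=alg, products=f1.products))
        shared_algs.add(alg)

    # fusions: maximal co-resident unit sets, matched at ALG granularity
    raw_shared: list[tuple[frozenset[str], FusionEvent, FusionEvent]] = []
    for f1 in e1.fusions:
        b1 = {alg_of(m): m for m in f1.members}
        for f2 in e2.fusions:
            b2 = {alg_of(m) for m in f2.members}
            common = set(b1) & b2
            if len(common) >= 2:
                raw_shared.append((frozenset(b1[a] for a in common), f1, f2))
    # drop strict subsets of other shared sets, dedupe
    kept: dict[frozenset[str], tuple[FusionEvent, FusionEvent]] = {}
    for members, f1, f2 in raw_shared:
        if any(members < other for other, _, _ in raw_shared):
            continue
        kept.setdefault(members, (f1, f2))
    shared_fusions = []
    attributed_1: dict[str, int] = {}
    attributed_2: dict[str, int] = {}
    for members in sorted(kept, key=sorted):
        f1, f2 = kept[members]
        chrom = "+".join(sorted(alg_of(m) for m in members))
        shared_fusions.append(FusionEvent(members=members, chromosome=chrom))
        attributed_1[f1.chromosome] = attributed_1.get(f1.chromosome, 0) + len(members) - 1
        attributed_2[f2.chromosome] = attributed_2.get(f2.chromosome, 0) + len(members) - 1

    def _specific(e: EventSet, shared_f: set[str], attributed: dict[str, int],
                  branch: tuple[str, str]) -> EventSet:
        fissions = tuple(f for f in e.fissions if f.alg not in shared_f)
        fusions = []
        for f in e.fusions:
            residual = (len(f.members) - 1) - attributed.get(f.chromosome, 0)
            if residual > 0:
                fusions.append(FusionEvent(members=f.members, chromosome=f.chromosome,
                                           tally=residual))
        return EventSet(branch=branch, fissions=fissions, fusions=tuple(fusions))

    mrca_label = f"mrca({e1.branch[1]},{e2.branch[1]})"
    shared = EventSet(
        branch=(e1.branch[0], mrca_label),
        fissions=tuple(shared_fissions),
        fusions=tuple(shared_fusions),
    )
    s1 = _specific(e1, shared_algs, attributed_1, (mrca_label, e1.branch[1]))
    s2 = _specific(e2, shared_algs, attributed_2, (mrca_label, e2.branch[1]))
    return MatchResult(shared, s1, s2, relabel_2)


# ---------------------------------------------------------------------------
# MRCA reconstruction
# ---------------------------------------------------------------------------


def _set_partitions(items: Sequence[str]):
    """All set partitions of ``items`` (restricted-growth-string order)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] | {first}] + smaller[i + 1:]
        yield smaller + [{first}]


def _distance_refined(p: KaryotypePartition, q: KaryotypePartition) -> int:
    """Fission+fusion distance, refining ``p`` onto ``q``'s universe if needed."""
    if p.units != q.units:
        p = refine_to_universe(p, q.units)
    f, u = count_events(p, q)
    return f + u


@dataclass
class ReconstructionResult:
    mrca: KaryotypePartition
    shared: EventSet
    lineage_specific: dict[str, EventSet]
    total_events: int
    distances: dict[str, int]
    certificate: dict
    consistent: bool
    missing_algs: dict[str, list[str]]

    def to_report_dict(self) -> dict:
        from .io_formats import _eventset_dict

        return {
            "kind": "reconstruction",
            "mrca": {
                "name": self.mrca.name,
                "n_chromosomes": len(self.mrca),
                "blocks": {c: sorted(b) for c, b in sorted(self.mrca.blocks.items())},
            },
            "shared": _eventset_dict(self.shared),
            "lineage_specific": {k: _eventset_dict(v) for k, v in self.lineage_specific.items()},
            "total_events": self.total_events,
            "distances": self.distances,
            "certificate": self.certificate,
            "consistent": self.consistent,
            "missing_algs": self.missing_algs,
        }


def _tree_sister_check(tree, lineages: Sequence[str]) -> None:
    tree.is_rooted = True
    taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = set(lineages) - taxa
    if missing:
        raise ValueError(f"tree is missing lineage tips: {sorted(missing)}")
    mrca = tree.mrca(taxon_labels=list(lineages))
    if mrca is tree.seed_node and len(taxa) > len(lineages):
        raise ValueError(
            f"lineages {sorted(lineages)} are not sisters in the tree; "
            "the reconstruction assumes ((lineage1, lineage2), outgroup)"
        )


def reconstruct_mrca(
    root: KaryotypePartition,
    paintings: Mapping[str, Painting],
    tree=None,
    gene_jaccard_min: float = 0.5,
    max_exhaustive: int = 8,
) -> ReconstructionResult:
    """Most parsimonious MRCA karyotype of two lineages descended from ``root``.

    Constructive: the MRCA is the root with only the lineage-shared events
    applied, so the total cost ``d(root, mrca) + d(mrca, k1) + d(mrca, k2)``
    is then certified — exhaustively over all candidate partitions when the
    unit universe has at most ``max_exhaustive`` units, otherwise by checking
    that no single split or merge of the MRCA lowers the total.
    """
    if len(paintings) != 2:
        raise ValueError("reconstruction needs exactly two lineage paintings")
    (name1, p1), (name2, p2) = sorted(paintings.items())
    if tree is not None:
        _tree_sister_check(tree, [name1, name2])

    e1 = extract_events(root, p1, branch=(root.name, name1))
    e2 = extract_events(root, p2, branch=(root.name, name2))
    match = match_shared_events(e1, e2, gene_jaccard_min=gene_jaccard_min)

    bases1 = {alg_of(u) for u in p1.to_partition().units}
    bases2 = {alg_of(u) for u in p2.to_partition().units}
    root_algs = {alg_of(u) for u in root.units}
    missing = {
        name1: sorted(root_algs - bases1),
        name2: sorted(root_algs - bases2),
    }
    common = bases1 & bases2
    root_common = KaryotypePartition(
        root.name,
        {c: b for c, b in root.blocks.items() if {alg_of(u) for u in b} <= common},
    )

    mrca = apply_events(root_common, match.shared, name="MRCA")
    k1 = p1.to_partition(name1)
    k2 = p2.to_partition(name2).relabel_units(match.relabel_2)

    def _restrict(k: KaryotypePartition) -> KaryotypePartition:
        blocks = {
            c: frozenset(u for u in b if alg_of(u) in common)
            for c, b in k.blocks.items()
        }
        return KaryotypePartition(k.name, {c: b for c, b in blocks.items() if b})

    k1, k2 = _restrict(k1), _restrict(k2)

    d_root = _distance_refined(root_common, mrca)
    d1 = _distance_refined(mrca, k1)
    d2 = _distance_refined(mrca, k2)
    total = d_root + d1 + d2

    # consistency: shared then specific reproduces each lineage karyotype
    consistent = True
    for spec, k in ((match.specific_1, k1), (match.specific_2, k2)):
        try:
            rebuilt = apply_events(mrca, spec)
            if refine_to_universe(rebuilt, k.units) != k:
                consistent = False
        except (ValueError, UniverseMismatchError):
            consistent = False

    certificate = _certify(root_common, mrca, k1, k2, total, max_exhaustive)

    return ReconstructionResult(
        mrca=mrca,
        shared=match.shared,
        lineage_specific={name1: match.specific_1, name2: match.specific_2},
        total_events=total,
        distances={"root_to_mrca": d_root, name1: d1, name2: d2},
        certificate=certificate,
        consistent=consistent,
        missing_algs=missing,
    )


def _common_universe(*parts: KaryotypePartition) -> set[str] | None:
    """Finest unit set spanned by all partitions, or None when labelings clash."""
    per_alg: dict[str, set[str]] = {}
    for p in parts:
        for u in p.units:
            per_alg.setdefault(alg_of(u), set()).add(u)
    universe: set[str] = set()
    for alg, units in per_alg.items():
        parts_only = {u for u in units if u != alg}
        if not parts_only:
            universe.add(alg)
        else:
            universe |= parts_only
    # verify every partition refines cleanly
    for p in parts:
        try:
            refine_to_universe(p, universe)
        except UniverseMismatchError:
            return None
    return universe


def _certify(root, mrca, k1, k2, total: int, max_exhaustive: int) -> dict:
    universe = _common_universe(root, mrca, k1, k2)
    if universe is None:
        return {"level": "none", "optimal": None,
                "note": "conflicting part labelings prevent a common universe"}

    root_u = refine_to_universe(root, universe)
    k1_u = refine_to_universe(k1, universe)
    k2_u = refine_to_universe(k2, universe)

    def cost(candidate: KaryotypePartition) -> int:
        return (
            sum(count_events(root_u, candidate))
            + sum(count_events(candidate, k1_u))
            + sum(count_events(candidate, k2_u))
        )

    if len(universe) <= max_exhaustive:
        items = sorted(universe)
        best, ties = None, 0
        for blocks in _set_partitions(items):
            cand = KaryotypePartition.from_block_sets("cand", blocks)
            c = cost(cand)
            if best is None or c < best:
                best, ties = c, 1
            elif c == best:
                ties += 1
        return {"level": "exhaustive", "optimal": bool(total == best),
                "minimum": best, "n_optima": ties}

    mrca_u = refine_to_universe(mrca, universe)
    for neighbor_blocks in _neighbors(mrca_u.block_sets()):
        cand = KaryotypePartition.from_block_sets("cand", neighbor_blocks)
        if cost(cand) < total:
            return {"level": "local", "optimal": False}
    return {"level": "local", "optimal": True}


# ---------------------------------------------------------------------------
# Inheritance classification
# ---------------------------------------------------------------------------


@dataclass
class InheritanceReport:
    classes: dict[str, str]  # chromosome -> "direct" | "derived"
    n_direct: int
    n_derived: int


def classify_inheritance(root: KaryotypePartition, painting: Painting) -> InheritanceReport:
    """Label each chromosome direct (one intact, unfused ALG) or derived.

    A chromosome directly inherits an ancestral linkage group exactly when
    its composition is a single unit that is an unfissioned ALG of the root;
    any fission product or multi-unit (fused) chromosome is derived.
    """
    root_algs = {alg_of(u) for u in root.units}
    classes: dict[str, str] = {}
    for chrom, units in painting.composition.items():
        direct = (
            len(units) == 1
            and units[0] == alg_of(units[0])
            and units[0] in root_algs
        )
        classes[chrom] = "direct" if direct else "derived"
    n_direct = sum(1 for v in classes.values() if v == "direct")
    return InheritanceReport(classes, n_direct, len(classes) - n_direct)
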