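"""Karyotypes as partitions of ancestral-linkage-group (ALG) part units.

A karyotype is modeled as a set partition: the universe is a set of atomic
units (an intact ALG such as ``ALG7``, or a fission product such as
``ALG2-1``), and each block of the partition is one chromosome.  Whole-block
splits (fissions) and merges (fusions) are the only moves of the model;
intrachromosomal rearrangements are invisible at this granularity.

The minimal number of fissions and fusions separating an ancestor partition
``p`` from a descendant ``q`` has a closed form through the *meet* (coarsest
common refinement) ``m`` of the two partitions::

    fissions = |m| - |p|        fusions = |m| - |q|

Minimality within the split/merge model is checked against an exhaustive
breadth-first-search oracle (:func:`bfs_distance`) in the test suite rather
than assumed.
"""

from __future__ import annotations

import itertools
import re
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

__all__ = [
    "alg_of",
    "KaryotypePartition",
    "EventCounts",
    "FissionEvent",
    "FusionEvent",
    "EventSet",
    "root_partition",
    "meet",
    "count_events",
    "bfs_distance",
    "best_common_refinement_distance",
    "apply_events",
    "refine_to_universe",
    "ancestral_grouping",
]

_PART_RE = re.compile(r"^(?P<alg>[^-]+)(?:-(?P<idx>\d+))?$")


def alg_of(unit: str) -> str:
    """Ancestral chromosome a unit label derives from (``ALG2-1`` -> ``ALG2``)."""
    m = _PART_RE.match(unit)
    if m is None:
        raise ValueError(f"malformed unit label: {unit!r}")
    return m.group("alg")


class UniverseMismatchError(ValueError):
    """Two partitions do not share the same unit universe."""

    def __init__(self, only_p: set[str], only_q: set[str]):
        self.only_p, self.only_q = only_p, only_q
        super().__init__(
            "unit universes differ; only in first: "
            f"{sorted(only_p)}; only in second: {sorted(only_q)}"
        )


@dataclass(frozen=True)
class KaryotypePartition:
    """A karyotype: named chromosomes, each a non-empty set of unit labels.

    Equality compares the unordered block structure (chromosome names are
    presentation only), which is what "block-identical karyotypes" means.
    """

    name: str
    blocks: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        blocks = {k: frozenset(v) for k, v in dict(self.blocks).items()}
        object.__setattr__(self, "blocks", blocks)
        seen: set[str] = set()
        for chrom, units in blocks.items():
            if not units:
                raise ValueError(f"empty chromosome block: {chrom}")
            dup = seen & units
            if dup:
                raise ValueError(f"units on more than one chromosome: {sorted(dup)}")
            seen |= units

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.blocks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KaryotypePartition):
            return NotImplemented
        return self.block_sets() == other.block_sets()

    def __hash__(self) -> int:
        return hash(self.block_sets())

    # -- views ---------------------------------------------------------------
    @property
    def units(self) -> frozenset[str]:
        return frozenset(u for b in self.blocks.values() for u in b)

    def block_sets(self) -> frozenset[frozenset[str]]:
        return frozenset(self.blocks.values())

    def chromosome_of(self, unit: str) -> str:
        for chrom, units in self.blocks.items():
            if unit in units:
                return chrom
        raise KeyError(unit)

    def rename(self, mapping: Mapping[str, str], name: str | None = None) -> "KaryotypePartition":
        """Rename chromosomes (missing keys keep their name)."""
        return KaryotypePartition(
            name or self.name,
            {mapping.get(c, c): u for c, u in self.blocks.items()},
        )

    def relabel_units(self, mapping: Mapping[str, str]) -> "KaryotypePartition":
        """Rename units (missing keys keep their label)."""
        return KaryotypePartition(
            self.name,
            {c: frozenset(mapping.get(u, u) for u in b) for c, b in self.blocks.items()},
        )

    @classmethod
    def from_block_sets(
        cls, name: str, blocks: Iterable[Iterable[str]], prefix: str = "chr"
    ) -> "KaryotypePartition":
        ordered = sorted((frozenset(b) for b in blocks), key=lambda b: sorted(b))
        return cls(name, {f"{prefix}{i + 1}": b for i, b in enumerate(ordered)})


def root_partition(n_alg: int = 17, labels: Sequence[str] | None = None) -> KaryotypePartition:
    """The ancestral karyotype: one chromosome per intact ALG (17 by default)."""
    labs = list(labels) if labels is not None else [f"ALG{i + 1}" for i in range(n_alg)]
    return KaryotypePartition("ALG-root", {lab: frozenset([lab]) for lab in labs})


def _check_universe(p: KaryotypePartition, q: KaryotypePartition) -> None:
    if p.units != q.units:
        raise UniverseMismatchError(set(p.units - q.units), set(q.units - p.units))


def meet(p: KaryotypePartition, q: KaryotypePartition) -> KaryotypePartition:
    """Coarsest common refinement: all non-empty pairwise block intersections."""
    _check_universe(p, q)
    blocks = []
    for bp in p.blocks.values():
        for bq in q.blocks.values():
            inter = bp & bq
            if inter:
                blocks.append(inter)
    return KaryotypePartition.from_block_sets(f"meet({p.name},{q.name})", blocks, prefix="m")


class EventCounts(NamedTuple):
    fissions: int
    fusions: int


def count_events(parent: KaryotypePartition, child: KaryotypePartition) -> EventCounts:
    """Minimal fission/fusion counts turning ``parent`` into ``child``.

    Both partitions must live on the same unit universe (use
    :func:`refine_to_universe` to express an ancestor on a descendant's part
    universe first).  Satisfies ``len(child) == len(parent) + fissions - fusions``.
    """
    m = meet(parent, child)
    return EventCounts(len(m) - len(parent), len(m) - len(child))


def event_distance(parent: KaryotypePartition, child: KaryotypePartition) -> int:
    f, u = count_events(parent, child)
    return f + u


def refine_to_universe(p: KaryotypePartition, universe: Iterable[str]) -> KaryotypePartition:
    """Express ``p`` on a finer unit universe.

    Each target unit must derive from exactly one unit of ``p`` — either the
    same label, or a part label whose prefix is a unit of ``p`` (``ALG10-2``
    derives from ``ALG10``).  Derived units stay in their ancestor's block, so
    the block structure is unchanged.
    """
    universe = set(universe)
    own = p.units
    mapping: dict[str, str] = {}
    for v in universe:
        if v in own:
            mapping[v] = v
            continue
        parent_unit = alg_of(v)
        if parent_unit in own:
            mapping[v] = parent_unit
        else:
            raise UniverseMismatchError(set(), {v})
    covered = set(mapping.values())
    missing = own - covered
    if missing:
        raise UniverseMismatchError(missing, set())
    blocks = {
        chrom: frozenset(v for v in universe if mapping[v] in units)
        for chrom, units in p.blocks.items()
    }
    return KaryotypePartition(p.name, blocks)


def ancestral_grouping(units: Iterable[str], name: str = "ancestor") -> KaryotypePartition:
    """Parent partition induced by grouping part units of each ancestral ALG."""
    groups: dict[str, set[str]] = {}
    for u in units:
        groups.setdefault(alg_of(u), set()).add(u)
    return KaryotypePartition(name, {alg: frozenset(us) for alg, us in groups.items()})


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FissionEvent:
    """One ancestral chromosome splitting into >= 2 product units.

    An ALG split into k parts is one recorded event contributing ``k - 1`` to
    the fission tally.  ``member_genes`` (reference-genome gene ids per
    product) enables gene-level breakpoint comparison between lineages.
    """

    alg: str
    products: tuple[str, ...]
    support: Mapping[str, int] | None = None
    member_genes: Mapping[str, frozenset[str]] | None = None

    def __post_init__(self) -> None:
        if len(self.products) < 2:
            raise ValueError("a fission needs at least two products")
        for prod in self.products:
            if alg_of(prod) != self.alg:
                raise ValueError(f"product {prod!r} does not derive from {self.alg!r}")

    @property
    def tally(self) -> int:
        return len(self.products) - 1


@dataclass(frozen=True)
class FusionEvent:
    """Units brought together on one descendant chromosome.

    A chromosome carrying m units contributes ``m - 1`` fusions; ``tally`` can
    be set lower when part of the joining is attributed elsewhere (e.g. a
    lineage-specific completion of a fusion whose core is shared).
    """

    members: frozenset[str]
    chromosome: str
    tally: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) < 2:
            raise ValueError("a fusion needs at least two members")
        t = self.tally if self.tally is not None else len(self.members) - 1
        if not (1 <= t <= len(self.members) - 1):
            raise ValueError(f"fusion tally {t} out of range for {len(self.members)} members")
        object.__setattr__(self, "tally", t)


@dataclass(frozen=True)
class EventSet:
    """Named fission and fusion events on one tree branch."""

    branch: tuple[str, str]
    fissions: tuple[FissionEvent, ...] = ()
    fusions: tuple[FusionEvent, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "fissions", tuple(self.fissions))
        object.__setattr__(self, "fusions", tuple(self.fusions))
        algs = [f.alg for f in self.fissions]
        if len(algs) != len(set(algs)):
            raise ValueError("more than one fission event for the same ALG on a branch")

    @property
    def n_fissions(self) -> int:
        return sum(f.tally for f in self.fissions)

    @property
    def n_fusions(self) -> int:
        return sum(f.tally for f in self.fusions)

    def is_empty(self) -> bool:
        return not self.fissions and not self.fusions


def apply_events(k: KaryotypePartition, events: EventSet, name: str | None = None) -> KaryotypePartition:
    """Apply an event script to a karyotype (fissions first, then fusions).

    A fission requires its ALG to sit alone on a chromosome (the model does
    not split fused chromosomes at ALG granularity); the chromosome is
    replaced by one singleton block per product, named after the product.  A
    fusion merges the blocks holding its members into one chromosome carrying
    the event's chromosome label.  ``len(result) == len(k) + fissions - fusions``.
    """
    blocks: dict[str, set[str]] = {c: set(b) for c, b in k.blocks.items()}

    for fis in events.fissions:
        home = None
        for chrom, units in blocks.items():
            if fis.alg in units:
                home = chrom
                break
        if home is None:
            raise ValueError(f"fission of {fis.alg!r}: unit not present in karyotype {k.name!r}")
        if blocks[home] != {fis.alg}:
            raise ValueError(
                f"fission of {fis.alg!r}: chromosome {home!r} carries other units "
                f"({sorted(blocks[home])}); fused chromosomes cannot fission in this model"
            )
        del blocks[home]
        for prod in fis.products:
            blocks[prod] = {prod}

    for fus in events.fusions:
        homes = []
        for member in sorted(fus.members):
            found = [c for c, units in blocks.items() if member in units]
            if not found:
                raise ValueError(f"fusion into {fus.chromosome!r}: unit {member!r} not present")
            homes.append(found[0])
        distinct = list(dict.fromkeys(homes))
        if len(distinct) < 2:
            raise ValueError(
                f"fusion into {fus.chromosome!r}: members {sorted(fus.members)} already "
                "co-resident (cannot fuse a chromosome with itself)"
            )
        merged: set[str] = set()
        for c in distinct:
            merged |= blocks.pop(c)
        blocks[fus.chromosome] = merged

    return KaryotypePartition(name or f"{k.name}+{events.branch[1]}",
                              {c: frozenset(b) for c, b in blocks.items()})


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def _neighbors(state: frozenset[frozenset[str]]):
    """All partitions one split or one merge away."""
    blocks = list(state)
    # merges
    for a, b in itertools.combinations(blocks, 2):
        yield (state - {a, b}) | {a | b}
    # splits: every bipartition of every block
    for blk in blocks:
        members = sorted(blk)
        if len(members) < 2:
            continue
        first, rest = members[0], members[1:]
        for r in range(len(rest) + 1):
            for combo in itertools.combinations(rest, r):
                part1 = frozenset((first, *combo))
                part2 = blk - part1
                if part2:
                    yield (state - {blk}) | {part1, part2}


def _split_moves(blk: frozenset[str]):
    members = sorted(blk)
    if len(members) < 2:
        return
    first, rest = members[0], members[1:]
    for r in range(len(rest) + 1):
        for combo in itertools.combinations(rest, r):
            part1 = frozenset((first, *combo))
            part2 = blk - part1
            if part2:
                yield part1, part2


def bfs_distance(parent: KaryotypePartition, child: KaryotypePartition, max_units: int = 8) -> int:
    """Shortest fission/fusion history length, by exhaustive breadth-first search.

    Moves are (a) splitting a block into two non-empty sub-blocks and
    (b) merging two blocks — with the model's no-breakpoint-reuse rule: a
    block created by a merge is never split again.  Without that rule a
    merge followed by a different resplit would realize a reciprocal
    translocation in two moves, an event type the fission/fusion model
    deliberately excludes (and which the closed-form count therefore does
    not minimize over).

    Test-only oracle; refuses universes larger than ``max_units``.
    """
    _check_universe(parent, child)
    if len(parent.units) > max_units:
        raise ValueError(f"universe of {len(parent.units)} units exceeds max_units={max_units}")
    start = (parent.block_sets(), frozenset())
    goal = child.block_sets()
    if start[0] == goal:
        return 0
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        (blocks, fused), d = frontier.popleft()
        nxt_states = []
        for a, b in itertools.combinations(blocks, 2):
            merged = a | b
            nxt_states.append(((blocks - {a, b}) | {merged}, (fused - {a, b}) | {merged}))
        for blk in blocks:
            if blk in fused:
                continue
            for part1, part2 in _split_moves(blk):
                nxt_states.append(((blocks - {blk}) | {part1, part2}, fused))
        for state in nxt_states:
            if state in seen:
                continue
            if state[0] == goal:
                return d + 1
            seen.add(state)
            frontier.append((state, d + 1))
    raise RuntimeError("unreachable: fissions to singletons then fusions reach any partition")


def best_common_refinement_distance(
    parent: KaryotypePartition, child: KaryotypePartition, max_units: int = 8
) -> int:
    """Minimal history cost by exhaustive search over common refinements.

    Every no-breakpoint-reuse history factors as fissions down to some
    common refinement r of both karyotypes followed by fusions, costing
    ``(|r| - |parent|) + (|r| - |child|)``; this enumerates all partitions
    of the universe and minimizes directly, independently of the meet
    construction.
    """
    _check_universe(parent, child)
    units = sorted(parent.units)
    if len(units) > max_units:
        raise ValueError(f"universe of {len(units)} units exceeds max_units={max_units}")

    def refines(r_blocks, coarse: KaryotypePartition) -> bool:
        return all(
            any(blk <= cb for cb in coarse.blocks.values()) for blk in r_blocks
        )

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for smaller in partitions(rest):
            for i in range(len(smaller)):
                yield smaller[:i] + [smaller[i] | {first}] + smaller[i + 1:]
            yield smaller + [{first}]

    best = None
    for blocks in partitions(units):
        fr = [frozenset(b) for b in blocks]
        if refines(fr, parent) and refines(fr, child):
            cost = (len(fr) - len(parent)) + (len(fr) - len(child))
            if best is None or cost < best:
                best = cost
    assert best is not None  # singletons always refine both
    return best
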