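"""Chromosome-level macrosynteny: contingency tables, homology tests, painting.

Homology between chromosomes of two genomes (or between chromosomes and
ancestral linkage groups) is decided from single-copy ortholog *membership*
only — which chromosome each partner sits on — so the analysis is independent
of intrachromosomal rearrangements.  A chromosome pair is called homologous
when its shared ortholog count is enriched under the upper-tail
hypergeometric test, after Benjamini-Hochberg FDR control over all cells,
and passes absolute-count and fraction gates that suppress translocation /
misassembly noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import ALGAssignment, GeneRecord, OrthologPair
from .karyotype import KaryotypePartition, alg_of

__all__ = [
    "ContingencyMatrix",
    "HomologyCall",
    "HomologyMap",
    "Painting",
    "build_contingency",
    "test_homology",
    "derive_homology_map",
    "paint_genome",
    "export_dotplot",
]


def _chrom_map(genes_or_algs) -> dict[str, str]:
    """gene_id -> chromosome (GeneRecords, placed only) or ALG (assignments)."""
    out: dict[str, str] = {}
    for g in genes_or_algs:
        if isinstance(g, ALGAssignment):
            out[g.gene_id] = g.alg
        elif isinstance(g, GeneRecord):
            if g.placed:
                out[g.gene_id] = g.chromosome
        else:
            raise TypeError(f"expected GeneRecord or ALGAssignment, got {type(g).__name__}")
    return out


@dataclass
class ContingencyMatrix:
    """Ortholog counts per (chromosome of A, chromosome/ALG of B) cell."""

    table: pd.DataFrame  # rows: chrom_a, cols: chrom_b or ALG, values: counts
    n_dropped: int = 0
    #: ortholog pairs backing each cell, as reference-side gene ids
    cell_genes: dict[tuple[str, str], frozenset[str]] | None = None

    @property
    def grand_total(self) -> int:
        return int(self.table.values.sum())

    @property
    def row_margins(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.table.sum(axis=0)


def build_contingency(
    genes_a: Sequence[GeneRecord],
    genes_b_or_alg,
    pairs: Iterable[OrthologPair],
    track_genes: bool = False,
) -> ContingencyMatrix:
    """Cross-tabulate ortholog pairs by chromosome of A x chromosome/ALG of B.

    Pairs referencing unknown or unplaced genes are dropped and counted in
    ``n_dropped``.  With ``track_genes`` the B-side gene ids backing every
    cell are kept (needed for gene-level event comparison downstream).
    """
    map_a = _chrom_map(genes_a)
    map_b = _chrom_map(genes_b_or_alg)
    rows_a, rows_b, kept_pairs = [], [], []
    dropped = 0
    for pa, pb in pairs:
        ca, cb = map_a.get(pa), map_b.get(pb)
        if ca is None or cb is None:
            dropped += 1
            continue
        rows_a.append(ca)
        rows_b.append(cb)
        kept_pairs.append((ca, cb, pb))
    if not rows_a:
        raise ValueError("no usable ortholog pairs (all unknown or unplaced)")
    table = pd.crosstab(pd.Series(rows_a, name="chrom_a"), pd.Series(rows_b, name="chrom_b"))
    table = table.sort_index().sort_index(axis=1)
    cell_genes = None
    if track_genes:
        acc: dict[tuple[str, str], set[str]] = {}
        for ca, cb, gb in kept_pairs:
            acc.setdefault((ca, cb), set()).add(gb)
        cell_genes = {k: frozenset(v) for k, v in acc.items()}
    return ContingencyMatrix(table, dropped, cell_genes)


@dataclass(frozen=True)
class HomologyCall:
    chrom_a: str
    chrom_b_or_alg: str
    count: int
    p_raw: float
    q_fdr: float
    significant: bool


def test_homology(
    matrix: ContingencyMatrix,
    alpha_fdr: float = 0.05,
    min_genes: int = 10,
    min_frac: float = 0.05,
) -> list[HomologyCall]:
    """Hypergeometric enrichment test for every contingency cell.

    For cell (i, j) with count k, row margin n, column margin K and grand
    total N, ``p_raw = P[X >= k]`` for X ~ Hypergeometric(N, K, n): the chance
    of drawing at least k genes of chromosome/ALG j when n genes are sampled
    from the pooled ortholog set.  q-values are Benjamini-Hochberg over all
    cells; a call is significant when ``q <= alpha_fdr``, ``k >= min_genes``
    and ``k / n >= min_frac``.

    A degenerate 1x1 matrix is a forced configuration: ``p_raw = 1`` by
    convention (flagged with a warning) and significance is decided by the
    count gates alone.
    """
    t = matrix.table
    N = matrix.grand_total
    degenerate = t.shape == (1, 1)
    if degenerate:
        warnings.warn("degenerate 1x1 contingency matrix; p_raw = 1 by convention", stacklevel=2)
    counts = t.values
    row_m = counts.sum(axis=1, keepdims=True)
    col_m = counts.sum(axis=0, keepdims=True)
    if degenerate:
        p = np.ones_like(counts, dtype=float)
    else:
        # upper tail P[X >= k] = sf(k - 1)
        p = hypergeom.sf(counts - 1, N, np.broadcast_to(col_m, counts.shape), row_m)
        p = np.clip(p, 0.0, 1.0)
    _, q_flat, _, _ = multipletests(p.ravel(), method="fdr_bh")
    q = q_flat.reshape(p.shape)
    frac = np.divide(counts, row_m, out=np.zeros(counts.shape, dtype=float),
                     where=row_m > 0)
    calls = []
    for i, ca in enumerate(t.index):
        for j, cb in enumerate(t.columns):
            k = int(counts[i, j])
            gates = k >= min_genes and frac[i, j] >= min_frac
            sig = bool(gates if degenerate else (q[i, j] <= alpha_fdr and gates))
            calls.append(HomologyCall(str(ca), str(cb), k, float(p[i, j]), float(q[i, j]), sig))
    return calls


@dataclass
class HomologyMap:
    """Significant chromosome homologies, with relation classes."""

    forward: dict[str, set[str]]   # chrom_a -> chroms_b
    inverse: dict[str, set[str]]   # chrom_b -> chroms_a
    relation: dict[tuple[str, str], str]  # (a, b) -> "1:1" | "1:2" | "2:1" | "complex"
    complex_pairs: list[tuple[str, str]]


def derive_homology_map(calls: Iterable[HomologyCall]) -> HomologyMap:
    """Keep significant calls and classify each homologous pair.

    ``1:2`` means one chromosome of A covers two of B (a fission on the B
    lineage or fusion on A); ``2:1`` the converse; anything where both sides
    have multiple partners is flagged ``complex`` for manual review.
    """
    forward: dict[str, set[str]] = {}
    inverse: dict[str, set[str]] = {}
    for c in calls:
        if not c.significant:
            continue
        forward.setdefault(c.chrom_a, set()).add(c.chrom_b_or_alg)
        inverse.setdefault(c.chrom_b_or_alg, set()).add(c.chrom_a)
    relation: dict[tuple[str, str], str] = {}
    complex_pairs: list[tuple[str, str]] = []
    for a, bs in forward.items():
        for b in bs:
            deg_a, deg_b = len(bs), len(inverse[b])
            if deg_a == 1 and deg_b == 1:
                rel = "1:1"
            elif deg_a > 1 and deg_b == 1:
                rel = "1:2"
            elif deg_a == 1 and deg_b > 1:
                rel = "2:1"
            else:
                rel = "complex"
                complex_pairs.append((a, b))
            relation[(a, b)] = rel
    return HomologyMap(forward, inverse, relation, sorted(complex_pairs))


def _alg_sort_key(unit: str) -> tuple:
    base = alg_of(unit)
    digits = "".join(ch for ch in base if ch.isdigit())
    part = unit[len(base):]
    part_idx = int(part[1:]) if part else 0
    return (int(digits) if digits else 10**9, base, part_idx)


@dataclass
class Painting:
    """Per-chromosome composition of a genome in ALG parts.

    ``composition`` maps each chromosome to its ordered ALG-part labels (an
    ALG significantly present on k >= 2 chromosomes yields parts ``-1..-k``
    in descending gene-support order; ties broken by chromosome label).
    Chromosomes with no significant ALG have an empty composition and are
    listed in ``flagged``.
    """

    genome_id: str
    composition: dict[str, list[str]]
    support: dict[str, int]
    members: dict[str, frozenset[str]] | None = None
    flagged: list[str] = field(default_factory=list)
    calls: list[HomologyCall] | None = None

    def to_partition(self, name: str | None = None) -> KaryotypePartition:
        blocks = {
            chrom: frozenset(units)
            for chrom, units in self.composition.items()
            if units
        }
        return KaryotypePartition(name or self.genome_id, blocks)

    def part_chromosome(self, unit: str) -> str:
        for chrom, units in self.composition.items():
            if unit in units:
                return chrom
        raise KeyError(unit)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Painting):
            return NotImplemented
        return (
            self.genome_id == other.genome_id
            and self.composition == other.composition
            and self.support == other.support
        )


def paint_genome(
    genes: Sequence[GeneRecord],
    alg_assign: Sequence[ALGAssignment],
    pairs: Iterable[OrthologPair],
    alpha_fdr: float = 0.05,
    min_genes: int = 10,
    min_frac: float = 0.05,
) -> Painting:
    """Paint a genome's chromosomes in ALG coordinates.

    Builds the chromosome x ALG ortholog contingency table, calls significant
    (chromosome, ALG) incidences with :func:`test_homology`, and names parts
    of ALGs split over several chromosomes.  Within a chromosome the
    composition is ordered by ALG number, matching the conventional painting
    layout.
    """
    genome_id = genes[0].genome_id if genes else "genome"
    matrix = build_contingency(genes, alg_assign, pairs, track_genes=True)
    calls = test_homology(matrix, alpha_fdr=alpha_fdr, min_genes=min_genes, min_frac=min_frac)

    # significant incidences per ALG, with support
    per_alg: dict[str, list[tuple[str, int]]] = {}
    for c in calls:
        if c.significant:
            per_alg.setdefault(c.chrom_b_or_alg, []).append((c.chrom_a, c.count))

    composition: dict[str, list[str]] = {chrom: [] for chrom in matrix.table.index.astype(str)}
    support: dict[str, int] = {}
    members: dict[str, frozenset[str]] = {}
    for alg, incidences in per_alg.items():
        incidences.sort(key=lambda t: (-t[1], t[0]))
        multi = len(incidences) > 1
        for idx, (chrom, count) in enumerate(incidences, start=1):
            unit = f"{alg}-{idx}" if multi else alg
            composition[chrom].append(unit)
            support[unit] = count
            if matrix.cell_genes is not None:
                members[unit] = matrix.cell_genes.get((chrom, alg), frozenset())
    for chrom in composition:
        composition[chrom].sort(key=_alg_sort_key)
    flagged = sorted(c for c, units in composition.items() if not units)
    return Painting(genome_id, composition, support, members or None, flagged, calls)


def export_dotplot(
    genes_a: Sequence[GeneRecord],
    genes_b: Sequence[GeneRecord],
    pairs: Iterable[OrthologPair],
    order_a: Sequence[str] | None = None,
    order_b: Sequence[str] | None = None,
    figure_path: str | None = None,
) -> pd.DataFrame:
    """Oxford dot-plot table: one row per ortholog pair at cumulative coordinates.

    Chromosome orders default to descending chromosome span.  With
    ``figure_path`` a scatter figure is also written (requires matplotlib).
    """

    def _layout(genes: Sequence[GeneRecord], order: Sequence[str] | None):
        placed = [g for g in genes if g.placed]
        spans: dict[str, int] = {}
        for g in placed:
            spans[g.chromosome] = max(spans.get(g.chromosome, 0), g.end)
        if order is None:
            order = sorted(spans, key=lambda c: (-spans[c], c))
        offsets, cum = {}, 0
        for chrom in order:
            offsets[chrom] = cum
            cum += spans.get(chrom, 0)
        return offsets, {g.gene_id: g for g in placed}

    off_a, by_id_a = _layout(genes_a, order_a)
    off_b, by_id_b = _layout(genes_b, order_b)
    rows = []
    for pa, pb in pairs:
        ga, gb = by_id_a.get(pa), by_id_b.get(pb)
        if ga is None or gb is None or ga.chromosome not in off_a or gb.chromosome not in off_b:
            continue
        rows.append(
            {
                "pair_id": f"{pa}|{pb}",
                "x": off_a[ga.chromosome] + (ga.start + ga.end) // 2,
                "y": off_b[gb.chromosome] + (gb.start + gb.end) // 2,
                "chrom_a": ga.chromosome,
                "chrom_b": gb.chromosome,
            }
        )
    df = pd.DataFrame(rows, columns=["pair_id", "x", "y", "chrom_a", "chrom_b"])
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        ax.scatter(df["x"], df["y"], s=2, alpha=0.5)
        ax.set_xlabel("cumulative position, genome A (bp)")
        ax.set_ylabel("cumulative position, genome B (bp)")
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return df
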