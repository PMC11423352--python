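"""Readers and writers for the external formats the pipeline touches.

Gene positions arrive as BED-like tables (``bed0``: 0-based half-open, the
BED convention; ``tsv1``: 1-based inclusive, converted on ingestion), single
copy ortholog pairs and ALG assignments as 2-column TSV, species trees as
Newick.  All coordinates are stored 0-based half-open internally.  Strand
(column 6) is accepted and ignored: the analysis depends only on chromosome
membership, not gene order or orientation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import dendropy
import pandas as pd

from .karyotype import EventSet, FissionEvent, FusionEvent, KaryotypePartition

__all__ = [
    "GeneRecord",
    "OrthologPair",
    "ALGAssignment",
    "read_gene_bed",
    "read_ortholog_table",
    "read_alg_table",
    "read_newick_tree",
    "write_newick_tree",
    "write_report",
    "read_painting",
    "read_karyotype",
    "read_eventset",
]

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchored to one chromosome of one genome (0-based half-open)."""

    genome_id: str
    chromosome: str
    start: int
    end: int
    gene_id: str
    placed: bool = True

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.gene_id}: negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end {self.end} <= start {self.start}")


class OrthologPair(NamedTuple):
    gene_a: str
    gene_b: str


@dataclass(frozen=True)
class ALGAssignment:
    gene_id: str
    alg: str


class MalformedLineError(ValueError):
    pass


def read_gene_bed(
    path: str | Path,
    genome_id: str,
    dialect: str = "bed0",
    chrom_allowlist: Iterable[str] | None = None,
) -> list[GeneRecord]:
    """Read a >=4-column gene position table into :class:`GeneRecord` s.

    ``dialect='bed0'`` takes coordinates as already 0-based half-open;
    ``'tsv1'`` converts from 1-based inclusive.  Genes on chromosomes outside
    ``chrom_allowlist`` (when given) are retained but flagged ``placed=False``
    so unanchored-scaffold leakage stays visible downstream.
    """
    if dialect not in ("bed0", "tsv1"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    allow = set(chrom_allowlist) if chrom_allowlist is not None else None
    records: list[GeneRecord] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track ", "browser ")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise MalformedLineError(
                    f"{path}:{lineno}: expected >=4 tab-separated columns, got {len(fields)}"
                )
            chrom, s, e, gene = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise MalformedLineError(f"{path}:{lineno}: non-integer coordinate") from exc
            if dialect == "tsv1":
                start -= 1
            if gene in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate gene_id {gene!r} (first seen line {seen[gene]})"
                )
            seen[gene] = lineno
            placed = allow is None or chrom in allow
            try:
                records.append(GeneRecord(genome_id, chrom, start, end, gene, placed))
            except ValueError as exc:
                raise MalformedLineError(f"{path}:{lineno}: {exc}") from exc
    return records


class OrthologTable(NamedTuple):
    pairs: list[OrthologPair]
    n_rejected: int


def read_ortholog_table(path: str | Path) -> OrthologTable:
    """Read a 2+-column TSV of ortholog pairs, keeping only single-copy pairs.

    A gene id appearing in more than one row (on either side) violates the
    single-copy assumption; all rows involving it are rejected and counted.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty ortholog table")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected >=2 columns, got {df.shape[1]}")
    if df.shape[1] > 2:
        warnings.warn(f"{path}: {df.shape[1]} columns; using the first two", stacklevel=2)
    a, b = df.iloc[:, 0], df.iloc[:, 1]
    dup_a = set(a[a.duplicated(keep=False)])
    dup_b = set(b[b.duplicated(keep=False)])
    keep = ~(a.isin(dup_a) | b.isin(dup_b))
    pairs = [OrthologPair(x, y) for x, y in zip(a[keep], b[keep])]
    return OrthologTable(pairs, int((~keep).sum()))


def read_alg_table(path: str | Path) -> list[ALGAssignment]:
    """Read a 2-column TSV mapping reference gene ids to ALG labels."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns")
    if df.iloc[:, 0].duplicated().any():
        dups = sorted(set(df.iloc[:, 0][df.iloc[:, 0].duplicated()]))
        raise ValueError(f"{path}: gene ids mapped to more than one ALG: {dups[:5]}")
    return [ALGAssignment(g, a) for g, a in zip(df.iloc[:, 0], df.iloc[:, 1])]


def read_newick_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; unlabeled internal nodes are auto-named.

    A trifurcating root on a 3-taxon tree means the tree is unrooted, which
    leaves the branch structure of the analysis undefined.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    root = tree.seed_node
    n_children = len(root.child_nodes())
    if n_children > 2:
        raise ValueError(
            f"tree root has {n_children} children (unrooted); re-root the tree, e.g. "
            "on the ALG reference outgroup, before the 3-taxon analysis"
        )
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.taxon is None and not node.label:
            counter += 1
            node.label = f"N{counter}"
    return tree


def write_newick_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# Report writing / round-tripping
# ---------------------------------------------------------------------------


def _painting_frame(p) -> pd.DataFrame:
    rows = []
    for chrom in sorted(p.composition):
        for unit in p.composition[chrom]:
            members = sorted(p.members.get(unit, ())) if p.members else []
            rows.append(
                {
                    "chromosome": chrom,
                    "alg_part": unit,
                    "gene_count": p.support.get(unit, 0),
                    "member_genes": ",".join(members),
                }
            )
    return pd.DataFrame(rows, columns=["chromosome", "alg_part", "gene_count", "member_genes"])


def _karyotype_frame(k: KaryotypePartition) -> pd.DataFrame:
    rows = [
        {"chromosome": chrom, "units": ",".join(sorted(units))}
        for chrom, units in sorted(k.blocks.items())
    ]
    return pd.DataFrame(rows, columns=["chromosome", "units"])


def _eventset_dict(e: EventSet) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "eventset",
        "branch": list(e.branch),
        "fissions": [
            {
                "alg": f.alg,
                "products": list(f.products),
                "support": dict(f.support) if f.support else None,
                "member_genes": (
                    {k: sorted(v) for k, v in f.member_genes.items()} if f.member_genes else None
                ),
            }
            for f in e.fissions
        ],
        "fusions": [
            {"members": sorted(f.members), "chromosome": f.chromosome, "tally": f.tally}
            for f in e.fusions
        ],
    }


def write_report(result, path: str | Path, format: str = "tsv") -> Path:
    """Serialize a pipeline product (deterministic field order).

    TSV for tabular products (paintings, karyotypes, homology calls, event
    tables, DataFrames); JSON for structured ones (event sets, reconstruction
    reports).  JSON reports carry a ``schema_version`` field.
    """
    from .synteny import Painting  # local import to avoid a cycle

    path = Path(path)
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown format {format!r}")

    if isinstance(result, EventSet):
        if format == "json":
            path.write_text(json.dumps(_eventset_dict(result), indent=1) + "\n")
        else:
            rows = [
                {"type": "fission", "alg_or_chrom": f.alg, "units": ",".join(f.products),
                 "tally": f.tally}
                for f in result.fissions
            ] + [
                {"type": "fusion", "alg_or_chrom": f.chromosome,
                 "units": ",".join(sorted(f.members)), "tally": f.tally}
                for f in result.fusions
            ]
            pd.DataFrame(rows, columns=["type", "alg_or_chrom", "units", "tally"]).to_csv(
                path, sep="\t", index=False
            )
    elif isinstance(result, Painting):
        frame = _painting_frame(result)
        if format == "tsv":
            frame.to_csv(path, sep="\t", index=False)
        else:
            path.write_text(
                json.dumps(
                    {
                        "schema_version": SCHEMA_VERSION,
                        "kind": "painting",
                        "genome_id": result.genome_id,
                        "rows": frame.to_dict(orient="records"),
                    },
                    indent=1,
                )
                + "\n"
            )
    elif isinstance(result, KaryotypePartition):
        frame = _karyotype_frame(result)
        if format == "tsv":
            frame.to_csv(path, sep="\t", index=False)
        else:
            path.write_text(
                json.dumps(
                    {
                        "schema_version": SCHEMA_VERSION,
                        "kind": "karyotype",
                        "name": result.name,
                        "rows": frame.to_dict(orient="records"),
                    },
                    indent=1,
                )
                + "\n"
            )
    elif isinstance(result, pd.DataFrame):
        if format == "tsv":
            result.to_csv(path, sep="\t", index=False)
        else:
            path.write_text(
                json.dumps(
                    {"schema_version": SCHEMA_VERSION, "kind": "table",
                     "rows": result.to_dict(orient="records")},
                    indent=1,
                )
                + "\n"
            )
    elif hasattr(result, "to_report_dict"):
        payload = {"schema_version": SCHEMA_VERSION, **result.to_report_dict()}
        if format == "json":
            path.write_text(json.dumps(payload, indent=1) + "\n")
        else:
            pd.json_normalize(payload).to_csv(path, sep="\t", index=False)
    elif isinstance(result, (list, tuple)):
        frame = pd.DataFrame([getattr(r, "__dict__", None) or r._asdict() for r in result])
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    return path


def read_painting(path: str | Path, genome_id: str):
    """Read back a painting TSV written by :func:`write_report`."""
    from .synteny import Painting

    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "alg_part": str})
    composition: dict[str, list[str]] = {}
    support: dict[str, int] = {}
    members: dict[str, frozenset[str]] = {}
    for row in df.itertuples(index=False):
        composition.setdefault(row.chromosome, []).append(row.alg_part)
        support[row.alg_part] = int(row.gene_count)
        cell = getattr(row, "member_genes", "")
        if isinstance(cell, str) and cell:
            members[row.alg_part] = frozenset(cell.split(","))
    return Painting(genome_id=genome_id, composition=composition, support=support,
                    members=members or None)


def read_karyotype(path: str | Path, name: str) -> KaryotypePartition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return KaryotypePartition(
        name, {r.chromosome: frozenset(r.units.split(",")) for r in df.itertuples(index=False)}
    )


def read_eventset(path: str | Path) -> EventSet:
    data = json.loads(Path(path).read_text())
    fissions = tuple(
        FissionEvent(
            alg=f["alg"],
            products=tuple(f["products"]),
            support=f.get("support"),
            member_genes=(
                {k: frozenset(v) for k, v in f["member_genes"].items()}
                if f.get("member_genes")
                else None
            ),
        )
        for f in data["fissions"]
    )
    fusions = tuple(
        FusionEvent(members=frozenset(f["members"]), chromosome=f["chromosome"], tally=f["tally"])
        for f in data["fusions"]
    )
    return EventSet(branch=tuple(data["branch"]), fissions=fissions, fusions=fusions)
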