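"""Plain-text interchange formats: GMT, RNK, matrix TSV, edge lists.

Parsing is strict and fails with file/line context — silent coercion is the
main reproducibility hazard in signature pipelines. All writers emit
canonical, round-trippable text.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError
from .regulators import GeneSetLibrary
from .signatures import ExpressionMatrix, GeneSetPair, RankedList
from .synthetic import GroundTruth


# ---------------------------------------------------------------- GMT

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: tab-separated ``term, description, genes…`` per line.

    Duplicate genes within a term are deduplicated (order kept) with a
    warning; duplicate term identifiers are a format error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line has {len(fields)} fields (need ≥ 3)",
                    path=str(path),
                    line=lineno,
                )
            term, _desc, *genes = fields
            if term in sets:
                raise FormatError(
                    f"duplicate term {term!r}", path=str(path), line=lineno
                )
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(
                    f"{path.name}:{lineno}: duplicated genes in term {term!r} deduplicated",
                    stacklevel=2,
                )
            sets[term] = unique
    return sets


def write_gmt(path, sets: Mapping[str, list], descriptions: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for term, genes in sets.items():
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc, *map(str, genes)]) + "\n")


def read_gene_set_library(path) -> GeneSetLibrary:
    return GeneSetLibrary.from_sets(read_gmt(path))


def read_gene_set_pair(path) -> GeneSetPair:
    """Read a two-line GMT whose terms end in UP / DOWN (case-insensitive)."""
    sets = read_gmt(path)
    if len(sets) != 2:
        raise FormatError(f"expected exactly 2 terms, found {len(sets)}", path=str(path))
    up = down = None
    origin = ""
    for term, genes in sets.items():
        upper = term.upper()
        if upper.endswith("UP"):
            up = frozenset(genes)
            origin = term[: -len("UP")].rstrip("_|")
        elif upper.endswith("DOWN"):
            down = frozenset(genes)
    if up is None or down is None:
        raise FormatError("terms must end in UP and DOWN", path=str(path))
    return GeneSetPair(up, down, origin=origin)


def write_gene_set_pair(path, pair: GeneSetPair) -> None:
    prefix = f"{pair.origin}_" if pair.origin else ""
    write_gmt(
        path,
        {f"{prefix}UP": sorted(pair.up_tags), f"{prefix}DOWN": sorted(pair.down_tags)},
    )


# ---------------------------------------------------------------- RNK

def read_rnk(path) -> RankedList:
    """Read a two-column RNK file in file order (no silent re-sorting)."""
    path = Path(path)
    genes: list[str] = []
    stats: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"RNK line has {len(fields)} fields (need 2)",
                    path=str(path),
                    line=lineno,
                )
            gene, stat = fields
            try:
                value = float(stat)
            except ValueError:
                raise FormatError(
                    f"non-numeric statistic {stat!r}", path=str(path), line=lineno
                ) from None
            genes.append(gene)
            stats.append(value)
    if not genes:
        raise FormatError("empty RNK file", path=str(path))
    return RankedList(np.array(genes, dtype=object), np.array(stats))


def write_rnk(path, ranked: RankedList) -> None:
    with Path(path).open("w") as fh:
        for gene, stat in zip(ranked.genes, ranked.stats):
            fh.write(f"{gene}\t{stat:.10g}\n")


# ---------------------------------------------------------------- matrices

def read_expression_tsv(path, groups_path=None, *, is_log: bool = False) -> ExpressionMatrix:
    """Read a genes × samples TSV (first column gene id) and optional labels."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - re-raise with location
        raise FormatError(f"unreadable matrix TSV: {exc}", path=str(path)) from exc
    groups = None
    if groups_path is not None:
        labels = pd.read_csv(groups_path, sep="\t", index_col=0)
        groups = labels.iloc[:, 0]
    return ExpressionMatrix(df, groups, is_log=is_log)


def write_expression_tsv(path, matrix: ExpressionMatrix, groups_path=None) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")
    if groups_path is not None and matrix.groups is not None:
        matrix.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")


def write_ground_truth(path, truth: GroundTruth) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# planted_compound\t{truth.planted_compound_id}\n")
        fh.write(f"# target_disease\t{truth.target_disease_id}\n")
        fh.write("gene\tdirection\n")
        for gene in sorted(truth.effect_genes):
            fh.write(f"{gene}\t{truth.effect_directions[gene]:+d}\n")


# ---------------------------------------------------------------- networks

def read_edge_list(path) -> nx.Graph:
    """Read a two-column TSV edge list into an undirected simple graph.

    Self-loops and duplicate edges are dropped with a warning.
    """
    path = Path(path)
    g = nx.Graph()
    loops = dupes = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"edge line has {len(fields)} fields (need 2)",
                    path=str(path),
                    line=lineno,
                )
            u, v = fields[0], fields[1]
            if u == v:
                loops += 1
                continue
            if g.has_edge(u, v):
                dupes += 1
                continue
            g.add_edge(u, v)
    if loops or dupes:
        warnings.warn(
            f"{path.name}: dropped {loops} self-loops and {dupes} duplicate edges",
            stacklevel=2,
        )
    return g
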