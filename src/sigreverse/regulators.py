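"""Upstream-regulator inference: TF enrichment → network expansion → kinases.

A simplified expression-to-kinases chain. Differentially expressed genes are
tested for overrepresentation of transcription-factor target sets
(one-sided hypergeometric / Fisher); the enriched TFs are expanded through a
protein–protein interaction network (all nodes on a path of bounded length
between two distinct seeds); the expanded subnetwork's nodes are then tested
against kinase–substrate sets with the same statistic. Libraries are
user-supplied GMT files (e.g. ChEA-style TF targets, KEA-style kinase
substrates); toy planted libraries ship with the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ConfigurationError, InputError
from .signatures import bh_adjust


@dataclass(frozen=True)
class GeneSetLibrary:
    """Term → gene-set mapping over a declared background universe."""

    sets: Mapping[str, frozenset]
    background: frozenset

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ConfigurationError(f"empty gene set for term {term!r}")
            if not genes <= self.background:
                raise ConfigurationError(f"term {term!r} has genes outside the background")

    @classmethod
    def from_sets(
        cls, sets: Mapping[str, Iterable], background: Iterable | None = None
    ) -> "GeneSetLibrary":
        frozen = {t: frozenset(g) for t, g in sets.items()}
        if background is None:
            bg: frozenset = frozenset().union(*frozen.values()) if frozen else frozenset()
        else:
            bg = frozenset(background)
        return cls(frozen, bg)


@dataclass
class NetworkExpansion:
    """Result of seed expansion: the induced subnetwork plus bookkeeping."""

    subnetwork: nx.Graph
    missing_seeds: tuple
    connected: bool  # False when no seed pair is linked within the bound


def _clean_network(network: nx.Graph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for u, v in network.edges:
        if u != v:
            g.add_edge(u, v)
    return g


def fisher_enrichment(query: Iterable, library: GeneSetLibrary) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of each term in the query.

    Query genes outside the background are dropped with a warning; an empty
    query after intersection is an input error. Rows are sorted by ascending
    p, ties broken by descending odds ratio then term identifier. q is BH
    across all terms of the library.
    """
    query = set(query)
    dropped = query - library.background
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the background were dropped",
            stacklevel=2,
        )
    query &= library.background
    if not query:
        raise InputError("query is empty after background intersection")
    big_n = len(library.background)
    n = len(query)
    rows = []
    for term, genes in library.sets.items():
        k = len(genes)
        overlap = len(genes & query)
        p = float(hypergeom.sf(overlap - 1, big_n, k, n))
        a, b = overlap, k - overlap
        c, d = n - overlap, big_n - k - n + overlap
        if b * c == 0:
            odds = np.inf if a * d > 0 else 0.0
        else:
            odds = (a * d) / (b * c)
        rows.append(
            {
                "term": term,
                "overlap": overlap,
                "term_size": k,
                "query_size": n,
                "background_size": big_n,
                "odds_ratio": odds,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["_neg_or"] = -table["odds_ratio"]
    table = table.sort_values(["p", "_neg_or", "term"], kind="mergesort")
    return table.drop(columns="_neg_or").reset_index(drop=True)


def expand_network(
    seed_terms: Iterable,
    network: nx.Graph,
    max_path_length: int = 2,
) -> NetworkExpansion:
    """Subnetwork induced by all nodes on short paths between seed pairs.

    A node belongs to the expansion when it lies on a simple path of length
    ≤ ``max_path_length`` (in edges) between two *distinct* seeds; the seeds
    present in the network are always included. Seeds absent from the network
    are reported, not fatal. If no seed pair is connected within the bound
    the expansion is returned empty and flagged.
    """
    if max_path_length < 1:
        raise ConfigurationError("max_path_length must be >= 1")
    seeds = sorted(set(seed_terms))
    g = _clean_network(network)
    present = [s for s in seeds if s in g]
    missing = tuple(s for s in seeds if s not in g)
    nodes: set = set()
    connected = False
    for s, t in combinations(present, 2):
        for path in nx.all_simple_paths(g, s, t, cutoff=max_path_length):
            connected = True
            nodes.update(path)
    if not connected:
        return NetworkExpansion(nx.Graph(), missing, False)
    nodes.update(present)
    return NetworkExpansion(g.subgraph(nodes).copy(), missing, True)


def kinase_enrichment(
    subnetwork_nodes: Iterable, kinase_library: GeneSetLibrary
) -> pd.DataFrame:
    """Kinase–substrate overrepresentation of the expanded subnetwork nodes."""
    nodes = set(subnetwork_nodes)
    if not nodes:
        raise InputError("empty subnetwork node set")
    return fisher_enrichment(nodes, kinase_library)


def expression_to_kinases(
    degs: Iterable,
    tf_library: GeneSetLibrary,
    network: nx.Graph,
    kinase_library: GeneSetLibrary,
    *,
    tf_q_threshold: float = 0.05,
    max_path_length: int = 2,
    max_tfs: int = 10,
) -> dict:
    """Run the full chain; returns the three tables plus the expansion.

    Enriched TFs (q below threshold, capped at ``max_tfs`` best-ranked) seed
    the network expansion. Path expansion needs at least two seeds, so when
    fewer pass the threshold the seed list is padded with the next
    best-ranked TFs up to two — the chain then always yields a kinase table
    on non-degenerate input.
    """
    tf_table = fisher_enrichment(degs, tf_library)
    seeds = list(tf_table.loc[tf_table["q"] < tf_q_threshold, "term"].head(max_tfs))
    for term in tf_table["term"]:
        if len(seeds) >= 2:
            break
        if term not in seeds:
            seeds.append(term)
    expansion = expand_network(seeds, network, max_path_length=max_path_length)
    if expansion.subnetwork.number_of_nodes() == 0:
        return {
            "tf": tf_table,
            "expansion": expansion,
            "kinase": pd.DataFrame(),
        }
    kin_table = kinase_enrichment(expansion.subnetwork.nodes, kinase_library)
    return {"tf": tf_table, "expansion": expansion, "kinase": kin_table}
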