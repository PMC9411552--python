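"""Louvain community detection on the known-plus-predicted subnetwork and
gene-set over-representation of the resulting communities.

Modularity uses edge weights (combined_score / 1000) when ``weighted``;
Louvain is the standard two-phase local-move + aggregation loop, with the
node visit order shuffled by the seed, so results are deterministic given
(graph, resolution, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import hypergeom

from .types import GeneSetCollection, PPIGraph

logger = logging.getLogger(__name__)


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    modularity: float
    resolution: float
    seed: int

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, community: int) -> set[str]:
        return {g for g, c in self.assignment.items() if c == community}


def subnetwork(graph: PPIGraph, known: Iterable[str], predicted: Iterable[str]) -> PPIGraph:
    """Induced subgraph on (known + predicted) genes present in the graph."""
    keep = (set(known) | set(predicted)) & set(graph.nodes)
    if not keep:
        raise ValueError("no known or predicted gene is present in the graph")
    return graph.subgraph(keep)


def _weight_arrays(graph: PPIGraph, weighted: bool) -> tuple[list[str], sp.csr_matrix]:
    nodes, a = graph.adjacency(weighted=weighted)
    return nodes, a


def modularity(
    graph: PPIGraph,
    partition: Mapping[str, int],
    resolution: float = 1.0,
    weighted: bool = True,
) -> float:
    """Newman modularity Q of a node -> community map.

    Q = (1/2m) * sum_ij [A_ij - resolution * k_i k_j / (2m)] delta(c_i, c_j).
    Undefined (error) on an edgeless graph.
    """
    if graph.n_edges == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    missing = [n for n in graph.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover node(s): {missing[:5]}")
    nodes, a = _weight_arrays(graph, weighted)
    comm = np.array([partition[n] for n in nodes])
    k = np.asarray(a.sum(axis=1)).ravel()
    two_m = k.sum()
    q = 0.0
    for c in np.unique(comm):
        mask = comm == c
        within = a[mask][:, mask].sum()
        k_c = k[mask].sum()
        q += within / two_m - resolution * (k_c / two_m) ** 2
    return float(q)


def _louvain_one_level(
    adj: sp.csr_matrix, resolution: float, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """One local-move phase; returns (community labels, any node moved)."""
    n = adj.shape[0]
    # aggregated self-loops already carry 2x the internal weight, so a plain
    # row sum is the correct louvain degree
    k = np.asarray(adj.sum(axis=1)).ravel()
    two_m = k.sum()
    comm = np.arange(n)
    comm_tot = k.copy()  # total degree per community
    indptr, indices, data = adj.indptr, adj.indices, adj.data
    moved_any = False
    improved = True
    while improved:
        improved = False
        for node in rng.permutation(n):
            c_old = comm[node]
            # weights from node to each neighbouring community (self-loop excluded)
            links: dict[int, float] = {}
            for ptr in range(indptr[node], indptr[node + 1]):
                j = indices[ptr]
                if j == node:
                    continue
                links[comm[j]] = links.get(comm[j], 0.0) + data[ptr]
            comm_tot[c_old] -= k[node]
            best_c, best_gain = c_old, links.get(c_old, 0.0) - resolution * comm_tot[c_old] * k[node] / two_m
            for c, w in links.items():
                if c == c_old:
                    continue
                gain = w - resolution * comm_tot[c] * k[node] / two_m
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            comm_tot[best_c] += k[node]
            if best_c != c_old:
                comm[node] = best_c
                improved = True
                moved_any = True
    # relabel to 0..n_comm-1
    _, labels = np.unique(comm, return_inverse=True)
    return labels, moved_any


def _aggregate(adj: sp.csr_matrix, labels: np.ndarray) -> sp.csr_matrix:
    n_comm = labels.max() + 1
    proj = sp.csr_matrix(
        (np.ones(len(labels)), (np.arange(len(labels)), labels)),
        shape=(len(labels), n_comm),
    )
    return (proj.T @ adj @ proj).tocsr()


def louvain(
    graph: PPIGraph,
    resolution: float = 1.0,
    seed: int = 0,
    weighted: bool = True,
) -> CommunityPartition:
    """Two-phase Louvain loop until no further modularity gain."""
    if graph.n_edges == 0:
        raise ValueError("louvain requires at least one edge")
    nodes, adj = _weight_arrays(graph, weighted)
    rng = np.random.default_rng(seed)
    node_labels = np.arange(len(nodes))
    level_adj = adj.copy()
    while True:
        labels, moved = _louvain_one_level(level_adj, resolution, rng)
        if not moved:
            break
        node_labels = labels[node_labels]
        level_adj = _aggregate(level_adj, labels)
        if level_adj.shape[0] == 1:
            break
    # canonical community ids: 0..K-1 in order of first appearance
    _, canonical = np.unique(node_labels, return_inverse=True)
    assignment = {n: int(c) for n, c in zip(nodes, canonical)}
    q = modularity(graph, assignment, resolution=resolution, weighted=weighted)
    return CommunityPartition(assignment=assignment, modularity=q, resolution=resolution, seed=seed)


def enrich_communities(
    partition: CommunityPartition,
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of every gene set in every community.

    Upper-tail p = P(X >= k) with population N = |universe|, K = |set in
    universe|, n = |community|; Benjamini-Hochberg adjustment pools all
    (community x set) rows. Sets disjoint from the universe are skipped with
    a warning.
    """
    universe = set(universe)
    members = {g for g in partition.assignment}
    if not members <= universe:
        raise ValueError("universe does not cover all community members")
    n_pop = len(universe)
    rows = []
    for c in sorted(set(partition.assignment.values())):
        comm = partition.members(c)
        for name in sets:
            in_universe = sets[name] & universe
            if not in_universe:
                logger.warning("gene set %s disjoint from universe; skipped", name)
                continue
            k = len(comm & in_universe)
            rows.append(
                {
                    "community": c,
                    "gene_set": name,
                    "overlap": k,
                    "set_size": len(in_universe),
                    "community_size": len(comm),
                    "universe_size": n_pop,
                    "pvalue": float(
                        hypergeom.sf(k - 1, n_pop, len(in_universe), len(comm))
                    ),
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["qvalue"] = benjamini_hochberg(df["pvalue"].to_numpy())
    return df


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values, clipped to 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running_min = min(running_min, p[i] * m / (rank + 1))
        adj[i] = running_min
    return adj
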