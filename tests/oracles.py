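"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity by the most literal method
available (dense iteration, exhaustive enumeration, naive running sums) and
share no code with the package implementations they check.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np


def dense_pagerank(
    adj: np.ndarray, seed_idx: Sequence[int], damping: float, n_iter: int = 200000,
    tol: float = 1e-15,
) -> np.ndarray:
    """Literal dense power iteration of r = a P^T r + a*dangling*v + (1-a) v."""
    n = adj.shape[0]
    out = adj.sum(axis=1)
    dangling = out == 0
    p = np.zeros_like(adj, dtype=float)
    nz = ~dangling
    p[nz] = adj[nz] / out[nz, None]
    v = np.zeros(n)
    v[list(seed_idx)] = 1.0 / len(seed_idx)
    r = v.copy()
    for _ in range(n_iter):
        rn = damping * (p.T @ r + r[dangling].sum() * v) + (1 - damping) * v
        if np.abs(rn - r).sum() < tol:
            return rn
        r = rn
    return r


def naive_enrichment_score(
    sorted_scores: Sequence[float], hit_flags: Sequence[bool], exponent: float
) -> float:
    """Walk the ranking one gene at a time and track the running-sum extremum."""
    total = sum(abs(s) ** exponent for s, h in zip(sorted_scores, hit_flags) if h)
    n = len(sorted_scores)
    n_hit = sum(hit_flags)
    if total == 0:
        total = float(n_hit)
        weights = [1.0 if h else 0.0 for h in hit_flags]
    else:
        weights = [abs(s) ** exponent if h else 0.0 for s, h in zip(sorted_scores, hit_flags)]
    miss = 1.0 / (n - n_hit)
    running = 0.0
    hi = lo = 0.0
    for s, h, w in zip(sorted_scores, hit_flags, weights):
        if h:
            running += w / total
        else:
            running -= miss
        hi = max(hi, running)
        lo = min(lo, running)
    # positive extremum wins (near-)ties in magnitude
    return hi if hi >= -lo - 1e-12 else lo


def confusion_counts(labels: Sequence[int], calls: Sequence[int]) -> tuple[int, int, int, int]:
    tp = fp = tn = fn = 0
    for y, c in zip(labels, calls):
        if y == 1 and c == 1:
            tp += 1
        elif y == 0 and c == 1:
            fp += 1
        elif y == 0 and c == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def pairwise_auroc(labels: Sequence[int], scores: Sequence[float]) -> float | None:
    """Probability a random positive outscores a random negative (ties = 1/2)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    if not pos or not neg:
        return None
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def set_partitions(n: int) -> Iterator[list[int]]:
    """All partitions of {0..n-1} as restricted-growth label lists."""
    labels = [0] * n

    def rec(i: int, max_label: int):
        if i == n:
            yield list(labels)
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0)


def unweighted_modularity(n_nodes: int, edges: Sequence[tuple[int, int]], labels: Sequence[int]) -> float:
    m = len(edges)
    deg = [0] * n_nodes
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    within = sum(1 for u, v in edges if labels[u] == labels[v])
    q = within / m
    for c in set(labels):
        d_c = sum(d for i, d in enumerate(deg) if labels[i] == c)
        q -= (d_c / (2 * m)) ** 2
    return q


def max_modularity_bruteforce(n_nodes: int, edges: Sequence[tuple[int, int]]) -> float:
    best = -1.0
    for labels in set_partitions(n_nodes):
        q = unweighted_modularity(n_nodes, edges, labels)
        if q > best:
            best = q
    return best
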