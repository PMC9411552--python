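import numpy as np
import pytest

from funcpred.types import GeneFeatureMatrix, LabelSet, PPIGraph


@pytest.fixture
def tiny_matrix() -> GeneFeatureMatrix:
    genes = ["g1", "g2", "g3", "g4"]
    feats = ["fA", "fB", "fC"]
    values = np.array(
        [
            [1, 0, 1],
            [0, 1, 1],
            [1, 1, 0],
            [0, 0, 0],
        ]
    )
    family = {"fA": "GTEx", "fB": "GO", "fC": "GTEx"}
    return GeneFeatureMatrix(genes, feats, values, family)


@pytest.fixture
def two_triangles() -> PPIGraph:
    edges = [
        ("a", "b", 1000), ("b", "c", 1000), ("a", "c", 1000),
        ("d", "e", 1000), ("e", "f", 1000), ("d", "f", 1000),
    ]
    return PPIGraph(list("abcdef"), edges)


@pytest.fixture
def joined_cliques() -> PPIGraph:
    """Two 5-cliques joined by a single edge."""
    nodes = [f"v{i}" for i in range(10)]
    edges = [(nodes[i], nodes[j], 1000) for i in range(5) for j in range(i + 1, 5)]
    edges += [(nodes[i], nodes[j], 1000) for i in range(5, 10) for j in range(i + 1, 10)]
    edges.append((nodes[4], nodes[5], 1000))
    return PPIGraph(nodes, edges)


def make_labels(positives, universe) -> LabelSet:
    return LabelSet.from_iterables(positives, universe)


def random_graph(n: int, p: float, seed: int, lo: int = 400, hi: int = 1000) -> PPIGraph:
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:03d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((nodes[i], nodes[j], int(rng.integers(lo, hi + 1))))
    return PPIGraph(nodes, edges)
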