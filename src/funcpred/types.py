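"""Shared domain types for the prediction pipeline.

All gene and feature identifiers are opaque strings matched case-sensitively;
no aliasing or namespace translation is performed anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _find_duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


class GeneFeatureMatrix:
    """Binary gene x attribute matrix with per-feature dataset-family tags.

    Parameters
    ----------
    gene_ids
        Ordered, unique row identifiers.
    feature_ids
        Ordered, unique column identifiers.
    values
        ``(n_genes, n_features)`` array; every entry must be 0 or 1.
    feature_family
        Maps every feature id to exactly one dataset-family label
        (e.g. ``"GTEx"``, ``"GO"``).
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        feature_ids: Sequence[str],
        values: np.ndarray,
        feature_family: Mapping[str, str],
    ) -> None:
        gene_ids = list(gene_ids)
        feature_ids = list(feature_ids)
        dups = _find_duplicates(gene_ids)
        if dups:
            raise FormatError(f"duplicate gene id(s): {dups}")
        dups = _find_duplicates(feature_ids)
        if dups:
            raise FormatError(f"duplicate feature id(s): {dups}")
        values = np.asarray(values)
        if values.shape != (len(gene_ids), len(feature_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(gene_ids)}, {len(feature_ids)})"
            )
        bad = (values != 0) & (values != 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary cell at gene {gene_ids[i]!r}, feature "
                f"{feature_ids[j]!r}: {values[i, j]!r}"
            )
        missing = [f for f in feature_ids if f not in feature_family]
        if missing:
            raise FormatError(f"feature(s) without family label: {missing[:5]}")
        self.gene_ids = gene_ids
        self.feature_ids = feature_ids
        self.values = values.astype(np.int8)
        self.feature_family = {f: feature_family[f] for f in feature_ids}
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}
        self._feature_index = {f: j for j, f in enumerate(feature_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._gene_index[g] for g in genes], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not in matrix") from None

    def feature_index(self, features: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._feature_index[f] for f in features], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"feature {e.args[0]!r} not in matrix") from None

    def submatrix(self, genes: Sequence[str], features: Sequence[str]) -> np.ndarray:
        """Dense 0/1 block for the given genes x features, in the given order."""
        return self.values[np.ix_(self.gene_index(genes), self.feature_index(features))]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneFeatureMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.values, other.values)
            and self.feature_family == other.feature_family
        )

    def __repr__(self) -> str:
        return f"<GeneFeatureMatrix {self.n_genes} genes x {self.n_features} features>"


@dataclass(frozen=True)
class LabelSet:
    """Positive gene ids (Class 1) within a gene universe; Class 0 is the rest."""

    positives: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        extra = self.positives - self.universe
        if extra:
            raise ValueError(f"positives outside the universe: {sorted(extra)[:5]}")

    @property
    def negatives(self) -> frozenset[str]:
        return self.universe - self.positives

    @staticmethod
    def from_iterables(positives: Iterable[str], universe: Iterable[str]) -> "LabelSet":
        return LabelSet(frozenset(positives), frozenset(universe))


@dataclass(frozen=True)
class Metrics:
    """Confusion counts plus the derived fractional scores.

    ``auroc`` is ``None`` when the evaluated truth contains a single class.
    ``precision``/``f1`` are 0 when their denominators are 0; ``fdr`` is 0
    when no gene was called positive.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    fpr: float
    fdr: float
    auroc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def from_counts(tp: int, fp: int, tn: int, fn: int, auroc: float | None = None) -> "Metrics":
        if min(tp, fp, tn, fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        n = tp + fp + tn + fn
        if n == 0:
            raise ValueError("empty confusion table")
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        return Metrics(
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
            accuracy=(tp + tn) / n,
            precision=precision,
            recall=recall,
            f1=f1,
            fpr=fp / (fp + tn) if fp + tn else 0.0,
            fdr=fp / (fp + tp) if fp + tp else 0.0,
            auroc=auroc,
        )


class PPIGraph:
    """Undirected weighted interaction graph with integer 0-1000 edge scores.

    Self-loops are rejected; an edge is stored once under the sorted node
    pair. Nodes may be isolated (present without edges).
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Mapping[tuple[str, str], int] | Iterable[tuple[str, str, int]],
    ) -> None:
        self.nodes: list[str] = list(dict.fromkeys(nodes))
        self._node_set = set(self.nodes)
        if isinstance(edges, Mapping):
            items = [(u, v, s) for (u, v), s in edges.items()]
        else:
            items = list(edges)
        self.edges: dict[tuple[str, str], int] = {}
        for u, v, score in items:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if not (0 <= int(score) <= 1000):
                raise ValueError(f"combined score {score} outside [0, 1000] for ({u}, {v})")
            if u not in self._node_set or v not in self._node_set:
                raise ValueError(f"edge endpoint not among nodes: ({u}, {v})")
            key = (u, v) if u <= v else (v, u)
            if key in self.edges:
                raise ValueError(f"duplicate edge {key}")
            self.edges[key] = int(score)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def subgraph(self, keep: Iterable[str]) -> "PPIGraph":
        keep_set = set(keep)
        nodes = [n for n in self.nodes if n in keep_set]
        edges = [
            (u, v, s)
            for (u, v), s in self.edges.items()
            if u in keep_set and v in keep_set
        ]
        return PPIGraph(nodes, edges)

    def adjacency(self, weighted: bool = True) -> tuple[list[str], sp.csr_matrix]:
        """Symmetric adjacency; weights are ``score / 1000`` when weighted else 1."""
        index = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        if not self.edges:
            return self.nodes, sp.csr_matrix((n, n))
        rows, cols, vals = [], [], []
        for (u, v), s in self.edges.items():
            w = s / 1000.0 if weighted else 1.0
            i, j = index[u], index[v]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        a = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        return self.nodes, a

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPIGraph):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and self.edges == other.edges

    def __repr__(self) -> str:
        return f"<PPIGraph {self.n_nodes} nodes, {self.n_edges} edges>"


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        members = frozenset(members)
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = members
        self.descriptions[name] = description

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.descriptions == other.descriptions
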