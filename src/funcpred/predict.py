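"""Genome-wide probability aggregation and high-confidence calling.

Every gene in the matrix is scored by every ensemble member and the per-gene
Class-1 probabilities are averaged. Genes that served as training negatives
for one member are still scored by all members: with many balanced blocks
the effect on the mean is negligible, so no exclusion is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import TrainedModelRecord
from .types import GeneFeatureMatrix


@dataclass
class EnsemblePrediction:
    model_type: str
    gene_ids: tuple[str, ...]
    mean_probability: np.ndarray  # aligned with gene_ids
    per_model: np.ndarray | None = None  # (n_models, n_genes)

    def __post_init__(self) -> None:
        p = np.asarray(self.mean_probability, dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if self.per_model is not None:
            if not np.allclose(self.per_model.mean(axis=0), p):
                raise ValueError("mean_probability inconsistent with per-model scores")

    @property
    def n_models(self) -> int:
        return 0 if self.per_model is None else self.per_model.shape[0]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.gene_ids, self.mean_probability.tolist()))

    def ranked(self) -> list[str]:
        """Gene ids by descending probability, ties broken by gene id."""
        score = self.as_dict()
        return sorted(self.gene_ids, key=lambda g: (-score[g], g))


def predict_genome(
    records: Sequence[TrainedModelRecord],
    matrix: GeneFeatureMatrix,
    merged_features: Sequence[str],
    keep_per_model: bool = True,
) -> EnsemblePrediction:
    """Score every gene with every record of one model type and average."""
    if not records:
        raise ValueError("no trained models supplied")
    model_type = records[0].model_type
    if any(r.model_type != model_type for r in records):
        raise ValueError("records mix model types")
    merged = tuple(merged_features)
    for r in records:
        if r.feature_ids != merged:
            raise ValueError(
                f"record (set {r.set_index}) trained on a different feature list"
            )
    genes = list(matrix.gene_ids)
    per_model = np.vstack([r.score_genes(matrix, genes) for r in records])
    return EnsemblePrediction(
        model_type=model_type,
        gene_ids=tuple(genes),
        mean_probability=per_model.mean(axis=0),
        per_model=per_model if keep_per_model else None,
    )


def top_fraction(pred: EnsemblePrediction, fraction: float = 0.01) -> set[str]:
    """High-confidence set: the top ``fraction`` of the probability distribution.

    The cutoff is the score at rank ``ceil(fraction * n)``; **all** genes
    scoring >= cutoff are included, so ties can only expand the set.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(pred.gene_ids)
    rank = math.ceil(fraction * n)
    scores = np.asarray(pred.mean_probability, dtype=float)
    cutoff = np.sort(scores)[::-1][rank - 1]
    return {g for g, s in zip(pred.gene_ids, scores) if s >= cutoff}


def ensemble_overlap(
    top_sets: Mapping[str, set[str]], min_models: int = 3
) -> tuple[set[str], dict[str, int]]:
    """Genes called high-confidence by at least ``min_models`` model types."""
    if min_models > len(top_sets):
        raise ValueError(
            f"min_models={min_models} exceeds the {len(top_sets)} available sets"
        )
    support: dict[str, int] = {}
    for s in top_sets.values():
        for g in s:
            support[g] = support.get(g, 0) + 1
    consensus = {g for g, c in support.items() if c >= min_models}
    return consensus, support


def top_candidates(
    pred: EnsemblePrediction, k: int = 100, exclude: set[str] | frozenset[str] = frozenset()
) -> list[str]:
    """Top ``k`` genes by mean probability after removing known positives."""
    if k < 1:
        raise ValueError("k must be >= 1")
    candidates = [g for g in pred.ranked() if g not in exclude]
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} available genes")
    return candidates[:k]


def prediction_frame(pred: EnsemblePrediction) -> pd.DataFrame:
    order = pred.ranked()
    score = pred.as_dict()
    df = pd.DataFrame({"gene_id": order, "mean_probability": [score[g] for g in order]})
    if pred.per_model is not None:
        idx = {g: i for i, g in enumerate(pred.gene_ids)}
        for m in range(pred.per_model.shape[0]):
            df[f"model_{m}"] = [pred.per_model[m, idx[g]] for g in order]
    return df
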