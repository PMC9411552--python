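"""Hold-out evaluation: balanced test sets, pooled rates, top-k rates.

Average metrics come from evaluating every ensemble member on every
balanced test set. Pooled rates come from averaging each held-out gene's
score across all members and thresholding once; the default 0.5 threshold
is the canonical choice for balanced training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .models import TrainedModelRecord, compute_metrics
from .types import GeneFeatureMatrix, LabelSet, Metrics


@dataclass
class HoldoutReport:
    per_pair: pd.DataFrame  # one row per (model, test set)
    averaged: dict[str, float]
    pooled_scores: dict[str, float]
    pooled_fpr: float
    threshold: float
    top_k: int | None = None
    top_k_fdr: float | None = None
    top_k_fpr: float | None = None


def evaluate_on_test_sets(
    records: Sequence[TrainedModelRecord],
    matrix: GeneFeatureMatrix,
    test_sets: Sequence[Sequence[str]],
    labels: LabelSet,
    train_genes: set[str] | frozenset[str] = frozenset(),
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Metrics for every (model, test set) pair, then the overall average.

    ``train_genes`` is a guard: any overlap with a test set is a hard error.
    """
    rows = []
    for test_set in test_sets:
        overlap = set(test_set) & set(train_genes)
        if overlap:
            raise ValueError(f"test genes overlap training genes: {sorted(overlap)[:5]}")
    for m_idx, record in enumerate(records):
        for t_idx, test_set in enumerate(test_sets):
            genes = list(test_set)
            y = [1 if g in labels.positives else 0 for g in genes]
            s = record.score_genes(matrix, genes)
            m = compute_metrics(y, s, threshold=threshold)
            rows.append(
                {
                    "model_index": m_idx,
                    "test_set_index": t_idx,
                    "accuracy": m.accuracy,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "auroc": m.auroc,
                }
            )
    per_pair = pd.DataFrame(rows)
    metric_cols = ["accuracy", "precision", "recall", "f1", "auroc"]
    averaged = {c: float(per_pair[c].mean()) for c in metric_cols}
    return per_pair, averaged


def pooled_scores(
    records: Sequence[TrainedModelRecord],
    matrix: GeneFeatureMatrix,
    genes: Sequence[str],
) -> dict[str, float]:
    """Per-gene mean Class-1 probability across all ensemble members."""
    scores = np.vstack([r.score_genes(matrix, list(genes)) for r in records]).mean(axis=0)
    return dict(zip(genes, scores.tolist()))


def pooled_holdout_rates(
    records: Sequence[TrainedModelRecord],
    matrix: GeneFeatureMatrix,
    pos_test: Sequence[str],
    neg_test: Sequence[str],
    threshold: float = 0.5,
) -> tuple[dict[str, float], Metrics]:
    """Pool the entire hold-out, average each gene's score, threshold once.

    Returns the pooled per-gene scores and the resulting Metrics
    (``metrics.fpr`` is the pooled FPR).
    """
    if not neg_test:
        raise ValueError("empty negative pool")
    genes = list(pos_test) + list(neg_test)
    scores = pooled_scores(records, matrix, genes)
    y = [1] * len(pos_test) + [0] * len(neg_test)
    s = [scores[g] for g in genes]
    return scores, compute_metrics(y, s, threshold=threshold)


def top_k_rates(
    scores: dict[str, float],
    positives: set[str] | frozenset[str],
    k: int = 25,
) -> tuple[float, float]:
    """(FDR, FPR) at the top-``k`` cut of the pooled mean scores.

    FDR = FP/(FP+TP) within the selection; FPR = FP/(FP+TN) over the whole
    pool. Ties break by gene id.
    """
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} scored genes")
    order = sorted(scores, key=lambda g: (-scores[g], g))
    selected = order[:k]
    tp = sum(1 for g in selected if g in positives)
    fp = k - tp
    n_neg = sum(1 for g in scores if g not in positives)
    fdr = fp / k if k else 0.0
    fpr = fp / n_neg if n_neg else 0.0
    return fdr, fpr


def build_holdout_report(
    records: Sequence[TrainedModelRecord],
    matrix: GeneFeatureMatrix,
    test_sets: Sequence[Sequence[str]],
    labels: LabelSet,
    pos_test: Sequence[str],
    neg_test: Sequence[str],
    train_genes: set[str] | frozenset[str] = frozenset(),
    threshold: float = 0.5,
    top_k: int = 25,
) -> HoldoutReport:
    per_pair, averaged = evaluate_on_test_sets(
        records, matrix, test_sets, labels, train_genes=train_genes, threshold=threshold
    )
    scores, pooled_metrics = pooled_holdout_rates(
        records, matrix, pos_test, neg_test, threshold=threshold
    )
    fdr, fpr = top_k_rates(scores, set(pos_test), k=top_k)
    return HoldoutReport(
        per_pair=per_pair,
        averaged=averaged,
        pooled_scores=scores,
        pooled_fpr=pooled_metrics.fpr,
        threshold=threshold,
        top_k=top_k,
        top_k_fdr=fdr,
        top_k_fpr=fpr,
    )
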