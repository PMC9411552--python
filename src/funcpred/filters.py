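"""Pre-training feature filters and the cross-set merge.

Two removal rules, evaluated per balanced training set:

* zero-fraction: a feature is removed when strictly more than
  ``max_zero_fraction`` of the set's genes are 0 for it;
* variance: a feature is kept when its population variance over the set is
  at least ``min_variance`` (inclusive). For a binary feature of frequency
  ``p`` the population variance is exactly ``p * (1 - p)``, so the default
  0.16 keeps frequencies in [0.2, 0.8].

Within a set the survivors of both rules are intersected; the final merged
feature list is the union of the per-set survivor lists and is fixed for
all subsequent training and prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import BalancedEnsembleDesign
from .types import GeneFeatureMatrix

DEFAULT_MAX_ZERO_FRACTION = 0.7
DEFAULT_MIN_VARIANCE = 0.16


@dataclass
class FilterReport:
    per_set_kept: list[list[str]]
    merged: list[str]
    max_zero_fraction: float
    min_variance: float

    def n_sets_kept(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for kept in self.per_set_kept:
            for f in kept:
                counts[f] = counts.get(f, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        counts = self.n_sets_kept()
        merged = set(self.merged)
        feats = sorted(counts)
        return pd.DataFrame(
            {
                "feature_id": feats,
                "n_sets_kept": [counts[f] for f in feats],
                "merged_flag": [int(f in merged) for f in feats],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _ones_count(matrix: GeneFeatureMatrix, gene_subset: Sequence[str]) -> np.ndarray:
    if len(gene_subset) == 0:
        raise ValueError("gene_subset is empty")
    rows = matrix.gene_index(gene_subset)
    return matrix.values[rows].sum(axis=0, dtype=np.int64)


def zero_fraction_filter(
    matrix: GeneFeatureMatrix,
    gene_subset: Sequence[str],
    max_zero_fraction: float = DEFAULT_MAX_ZERO_FRACTION,
) -> list[str]:
    """Feature ids whose zero fraction over the subset is <= the threshold."""
    ones = _ones_count(matrix, gene_subset)
    n = len(gene_subset)
    zero_frac = (n - ones) / n
    keep = zero_frac <= max_zero_fraction
    return [f for f, k in zip(matrix.feature_ids, keep) if k]


def variance_filter(
    matrix: GeneFeatureMatrix,
    gene_subset: Sequence[str],
    min_variance: float = DEFAULT_MIN_VARIANCE,
) -> list[str]:
    """Feature ids with population variance >= min_variance (inclusive).

    Computed exactly from integer one-counts as ``k * (n - k) / n**2`` so
    boundary frequencies (e.g. 0.2 with variance 0.16) are kept without
    floating-point surprises.
    """
    ones = _ones_count(matrix, gene_subset)
    n = len(gene_subset)
    var = ones * (n - ones) / float(n) ** 2
    keep = var >= min_variance
    return [f for f, k in zip(matrix.feature_ids, keep) if k]


def select_features(
    matrix: GeneFeatureMatrix,
    design: BalancedEnsembleDesign,
    max_zero_fraction: float = DEFAULT_MAX_ZERO_FRACTION,
    min_variance: float = DEFAULT_MIN_VARIANCE,
) -> FilterReport:
    """Apply both filters per training set, intersect within a set, union across sets.

    Deterministic given matrix and design. Raises if the merged list is empty.
    """
    per_set_kept: list[list[str]] = []
    merged: set[str] = set()
    for training_set in design.training_sets:
        zf = set(
            zero_fraction_filter(matrix, training_set, max_zero_fraction)
        )
        vf = set(variance_filter(matrix, training_set, min_variance))
        kept = [f for f in matrix.feature_ids if f in zf and f in vf]
        per_set_kept.append(kept)
        merged.update(kept)
    if not merged:
        raise ValueError(
            "feature filtering removed every feature; no merged list can be formed"
        )
    merged_ordered = [f for f in matrix.feature_ids if f in merged]
    return FilterReport(per_set_kept, merged_ordered, max_zero_fraction, min_variance)
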