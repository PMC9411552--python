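"""The five classifier types, their tuning protocols, CV and metrics.

Model types: LR (logistic regression), GNB (Gaussian naive Bayes),
SVM (support-vector machine with Platt-calibrated probabilities),
RF (random forest), GB (gradient boosting).

Tuning protocols:

* SVM — 3-fold grid search over kernel (linear or RBF), cost and RBF
  bandwidth;
* RF — grid search over tree count, then randomized search over
  max features per split, max depth, min samples to split and min samples
  per leaf;
* GB — grid search over learning rate and tree count, then the same
  randomized tree-parameter search;
* LR / GNB — library defaults, no search.

Set ``ModelSpec.tuning = "none"`` to skip all searches (library defaults
throughout), which is the fast desk-scale mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, RandomizedSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .types import GeneFeatureMatrix, LabelSet, Metrics

logger = logging.getLogger(__name__)

MODEL_TYPES = ("LR", "GNB", "SVM", "RF", "GB")

# default search spaces; the source protocol names the tuned parameters but
# not the grids, so these stay small enough for desk-scale runs
DEFAULT_SEARCH: dict[str, dict[str, Any]] = {
    "SVM": {
        "grid": [
            {"kernel": ["linear"], "C": [0.1, 1, 10, 100]},
            {"kernel": ["rbf"], "C": [0.1, 1, 10, 100], "gamma": [0.001, 0.01, 0.1, 1]},
        ]
    },
    "RF": {
        "grid": {"n_estimators": [100, 200, 500]},
        "random": {
            "max_features": ["sqrt", "log2", None],
            "max_depth": [None, 3, 5, 10, 20],
            "min_samples_split": [2, 4, 8],
            "min_samples_leaf": [1, 2, 4],
        },
    },
    "GB": {
        "grid": {"learning_rate": [0.01, 0.1, 0.3], "n_estimators": [100, 200, 500]},
        "random": {
            "max_features": ["sqrt", "log2", None],
            "max_depth": [2, 3, 5, 10],
            "min_samples_split": [2, 4, 8],
            "min_samples_leaf": [1, 2, 4],
        },
    },
}


@dataclass(frozen=True)
class ModelSpec:
    model_type: str
    seed: int = 0
    tuning: str = "paper"  # "paper" = full search protocol, "none" = defaults
    search: Mapping[str, Any] | None = None  # overrides DEFAULT_SEARCH[model_type]
    n_random_draws: int = 20
    tune_folds: int = 3

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"model_type must be one of {MODEL_TYPES}, got {self.model_type!r}")
        if self.tuning not in ("paper", "none"):
            raise ValueError(f"tuning must be 'paper' or 'none', got {self.tuning!r}")
        if self.tuning == "paper" and self.model_type in ("SVM", "RF", "GB"):
            space = self.search if self.search is not None else DEFAULT_SEARCH[self.model_type]
            if not space:
                raise ValueError(f"empty search space for tunable model {self.model_type}")

    def space(self) -> Mapping[str, Any]:
        return self.search if self.search is not None else DEFAULT_SEARCH.get(self.model_type, {})


@dataclass
class TrainedModelRecord:
    model_type: str
    set_index: int
    params: dict[str, Any]
    estimator: Any
    feature_ids: tuple[str, ...]
    seed: int

    @property
    def feature_importances(self) -> np.ndarray | None:
        imp = getattr(self.estimator, "feature_importances_", None)
        return None if imp is None else np.asarray(imp, dtype=float)

    def score_genes(self, matrix: GeneFeatureMatrix, genes: Sequence[str]) -> np.ndarray:
        """Class-1 probability for each gene, using this record's feature list."""
        x = matrix.submatrix(genes, list(self.feature_ids)).astype(np.float64)
        proba = self.estimator.predict_proba(x)
        class_one = list(self.estimator.classes_).index(1)
        return proba[:, class_one]


@dataclass
class CVMetrics:
    model_type: str
    k: int
    per_fold: pd.DataFrame  # one row per fold: accuracy..auroc
    means: dict[str, float]
    sds: dict[str, float]

    METRICS = ("accuracy", "precision", "recall", "f1", "auroc")


def _base_estimator(model_type: str, seed: int) -> Any:
    if model_type == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if model_type == "GNB":
        return GaussianNB()
    if model_type == "SVM":
        # Platt-style probability calibration on training folds
        return CalibratedClassifierCV(SVC(random_state=seed), ensemble=False)
    if model_type == "RF":
        return RandomForestClassifier(random_state=seed)
    if model_type == "GB":
        return GradientBoostingClassifier(random_state=seed)
    raise ValueError(f"unknown model type {model_type!r}")


def _design_matrix(
    matrix: GeneFeatureMatrix, genes: Sequence[str], features: Sequence[str], labels: LabelSet
) -> tuple[np.ndarray, np.ndarray]:
    x = matrix.submatrix(genes, features).astype(np.float64)
    y = np.array([1 if g in labels.positives else 0 for g in genes])
    if len(set(y)) < 2:
        raise ValueError("training set must contain both classes")
    return x, y


def tune_and_train(
    spec: ModelSpec,
    matrix: GeneFeatureMatrix,
    training_set: Sequence[str],
    merged_features: Sequence[str],
    labels: LabelSet,
    set_index: int = 0,
) -> TrainedModelRecord:
    """Tune (per the model type's protocol) and fit one ensemble member."""
    x, y = _design_matrix(matrix, training_set, merged_features, labels)
    est = _base_estimator(spec.model_type, spec.seed)
    chosen: dict[str, Any] = {}
    if spec.tuning == "paper" and spec.model_type in ("SVM", "RF", "GB"):
        cv = StratifiedKFold(n_splits=spec.tune_folds, shuffle=True, random_state=spec.seed)
        space = spec.space()
        # the SVM grid is searched on the bare SVC, then re-wrapped for calibration
        searched = SVC(random_state=spec.seed) if spec.model_type == "SVM" else est
        grid = GridSearchCV(searched, space["grid"], cv=cv, scoring="accuracy", n_jobs=1)
        grid.fit(x, y)
        chosen.update(grid.best_params_)
        if spec.model_type == "SVM":
            est = CalibratedClassifierCV(
                SVC(random_state=spec.seed, **grid.best_params_), ensemble=False
            )
        else:
            est = clone(est).set_params(**grid.best_params_)
        if spec.model_type != "SVM" and "random" in space and space["random"]:
            space_size = 1
            for v in space["random"].values():
                space_size *= len(v)
            rand = RandomizedSearchCV(
                est,
                space["random"],
                n_iter=min(spec.n_random_draws, space_size),
                cv=cv,
                scoring="accuracy",
                random_state=spec.seed,
                n_jobs=1,
            )
            rand.fit(x, y)
            chosen.update(rand.best_params_)
            est = clone(est).set_params(**rand.best_params_)
    est.fit(x, y)
    return TrainedModelRecord(
        model_type=spec.model_type,
        set_index=set_index,
        params=chosen,
        estimator=est,
        feature_ids=tuple(merged_features),
        seed=spec.seed,
    )


def compute_metrics(
    truth: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> Metrics:
    """Confusion-table metrics at ``score >= threshold`` plus midrank AUROC.

    AUROC uses the Mann-Whitney rank statistic with midranks for ties and is
    ``None`` (flagged, not an error) when the truth has a single class.
    """
    y = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("truth and scores must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("truth labels must be 0/1")
    if ((s < 0) | (s > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        auroc = None
    else:
        ranks = rankdata(s)  # midranks
        auroc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return Metrics.from_counts(tp, fp, tn, fn, auroc=auroc)


def cross_validate(
    spec: ModelSpec,
    matrix: GeneFeatureMatrix,
    training_set: Sequence[str],
    merged_features: Sequence[str],
    labels: LabelSet,
    k: int = 10,
    seed: int | None = None,
    params: Mapping[str, Any] | None = None,
) -> CVMetrics:
    """Stratified k-fold CV; metrics computed out-of-fold per fold then averaged."""
    if len(training_set) < k:
        raise ValueError(f"training set of {len(training_set)} smaller than k={k}")
    x, y = _design_matrix(matrix, training_set, merged_features, labels)
    seed = spec.seed if seed is None else seed
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for train_idx, test_idx in skf.split(x, y):
        est = _base_estimator(spec.model_type, spec.seed)
        if params:
            est.set_params(**params)
        est.fit(x[train_idx], y[train_idx])
        class_one = list(est.classes_).index(1)
        fold_scores = est.predict_proba(x[test_idx])[:, class_one]
        m = compute_metrics(y[test_idx], fold_scores)
        if m.auroc is None:
            raise ValueError("a CV fold contains a single class; increase set size or lower k")
        rows.append(
            {
                "accuracy": m.accuracy,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "auroc": m.auroc,
            }
        )
    per_fold = pd.DataFrame(rows)
    means = {c: float(per_fold[c].mean()) for c in CVMetrics.METRICS}
    sds = {c: float(per_fold[c].std(ddof=0)) for c in CVMetrics.METRICS}
    return CVMetrics(model_type=spec.model_type, k=k, per_fold=per_fold, means=means, sds=sds)


def ensemble_cv_table(results: Mapping[str, Sequence[CVMetrics]]) -> pd.DataFrame:
    """Per model type, metric means and sds averaged across the training-set
    ensemble; rows sorted by model type name."""
    rows = []
    for model_type in sorted(results):
        cvs = results[model_type]
        if not cvs:
            raise ValueError(f"no CV results for model type {model_type}")
        row: dict[str, Any] = {"model_type": model_type}
        for metric in CVMetrics.METRICS:
            row[f"{metric}_mean"] = float(np.mean([c.means[metric] for c in cvs]))
            row[f"{metric}_sd"] = float(np.mean([c.sds[metric] for c in cvs]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("model_type")


def rank_features(
    records: Sequence[TrainedModelRecord],
    feature_family: Mapping[str, str],
    top_k: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average tree-model importances across the ensemble and rank features.

    Returns ``(ranked, family_counts)``: the top ``top_k`` features by mean
    importance, and per-family counts of appearances in each model's
    individual top-``top_k`` list. Records without importances are excluded
    with a warning; all-excluded is an error.
    """
    usable = [r for r in records if r.feature_importances is not None]
    for r in records:
        if r.feature_importances is None:
            logger.warning(
                "model %s (set %d) has no feature importances; excluded from ranking",
                r.model_type, r.set_index,
            )
    if not usable:
        raise ValueError("no model with feature importances")
    feats = usable[0].feature_ids
    for r in usable[1:]:
        if r.feature_ids != feats:
            raise ValueError("records disagree on the feature list")
    imp = np.vstack([r.feature_importances for r in usable])
    mean_imp = imp.mean(axis=0)
    order = np.argsort(-mean_imp, kind="stable")[:top_k]
    ranked = pd.DataFrame(
        {
            "feature_id": [feats[i] for i in order],
            "mean_importance": mean_imp[order],
        }
    )
    fam_rows = []
    for m in range(len(usable)):
        top = np.argsort(-imp[m], kind="stable")[:top_k]
        counts: dict[str, int] = {}
        for i in top:
            fam = feature_family[feats[i]]
            counts[fam] = counts.get(fam, 0) + 1
        for fam, c in sorted(counts.items()):
            fam_rows.append({"model_index": m, "family": fam, "count": c})
    return ranked, pd.DataFrame(fam_rows)
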