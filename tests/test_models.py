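import itertools

import numpy as np
import pytest

from funcpred import synthetic as syn
from funcpred.models import (
    MODEL_TYPES,
    CVMetrics,
    ModelSpec,
    compute_metrics,
    cross_validate,
    ensemble_cv_table,
    rank_features,
    tune_and_train,
)
from funcpred.types import GeneFeatureMatrix, LabelSet

from .oracles import confusion_counts, pairwise_auroc

TINY_SEARCH = {
    "SVM": {"grid": [{"kernel": ["linear"], "C": [1, 10]}]},
    "RF": {"grid": {"n_estimators": [20]}, "random": {"max_depth": [2, 4]}},
    "GB": {"grid": {"learning_rate": [0.1], "n_estimators": [20]},
           "random": {"max_depth": [2, 3]}},
}


def separable_fixture(n=40):
    """Feature f0 equals the label; f1 is noise."""
    genes = [f"g{i:03d}" for i in range(n)]
    rng = np.random.default_rng(0)
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    vals = np.column_stack([y, rng.integers(0, 2, n)]).astype(np.int8)
    m = GeneFeatureMatrix(genes, ["f0", "f1"], vals, {"f0": "A", "f1": "A"})
    labels = LabelSet.from_iterables(
        [g for g, yy in zip(genes, y) if yy == 1], genes
    )
    return m, labels


def signal_fixture(seed=0, n_genes=300, n_pos=60, p1=0.9, p0=0.01, n_sig=8):
    cfg = syn.SyntheticConfig(
        seed=seed, n_genes=n_genes, n_positives=n_pos,
        families=(syn.FamilyConfig("famA", n_sig, p0, n_sig),),
        signal_rate=p1,
    )
    return syn.generate_feature_matrix(cfg)


class TestTuneAndTrain:
    @pytest.mark.parametrize("model_type", MODEL_TYPES)
    def test_separable_training_accuracy_one(self, model_type):
        m, labels = separable_fixture()
        spec = ModelSpec(model_type, seed=1, tuning="paper",
                         search=TINY_SEARCH.get(model_type))
        rec = tune_and_train(spec, m, m.gene_ids, m.feature_ids, labels)
        scores = rec.score_genes(m, m.gene_ids)
        y = np.array([1 if g in labels.positives else 0 for g in m.gene_ids])
        acc = np.mean((scores >= 0.5).astype(int) == y)
        assert acc == 1.0

    def test_identical_seed_identical_hyperparameters(self):
        m, labels = signal_fixture()
        spec = ModelSpec("GB", seed=5, tuning="paper", search=TINY_SEARCH["GB"],
                         n_random_draws=2)
        r1 = tune_and_train(spec, m, m.gene_ids, m.feature_ids, labels)
        r2 = tune_and_train(spec, m, m.gene_ids, m.feature_ids, labels)
        assert r1.params == r2.params

    def test_gnb_scores_in_unit_interval_and_permutation_invariant(self):
        m, labels = signal_fixture()
        spec = ModelSpec("GNB", seed=0, tuning="none")
        rec = tune_and_train(spec, m, m.gene_ids, m.feature_ids, labels)
        s1 = rec.score_genes(m, m.gene_ids)
        assert ((s1 >= 0) & (s1 <= 1)).all()
        # permute feature columns; ordering of gene scores must be unchanged
        perm = list(reversed(m.feature_ids))
        rec2 = tune_and_train(spec, m, m.gene_ids, perm, labels)
        s2 = rec2.score_genes(m, m.gene_ids)
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_single_class_rejected(self):
        m, labels = separable_fixture()
        pos = sorted(labels.positives)
        with pytest.raises(ValueError, match="both classes"):
            tune_and_train(ModelSpec("LR", tuning="none"), m, pos, m.feature_ids, labels)


class TestComputeMetrics:
    def test_paper_pooled_fpr(self):
        # 425 false positives among 5,368 negatives
        y = [0] * 5368
        s = [0.9] * 425 + [0.1] * (5368 - 425)
        m = compute_metrics(y, s)
        assert m.fpr == pytest.approx(425 / 5368)
        assert round(m.fpr, 3) == 0.079

    def test_paper_top25_fdr_arithmetic(self):
        # 14 FP and 11 TP selected
        y = [1] * 11 + [0] * 14
        s = [1.0] * 25
        m = compute_metrics(y, s)
        assert m.fdr == pytest.approx(14 / 25) == pytest.approx(0.56)

    def test_perfect_scores(self):
        y = [0, 1, 0, 1, 1]
        m = compute_metrics(y, [float(v) for v in y])
        assert (m.accuracy, m.precision, m.recall, m.f1, m.auroc) == (1, 1, 1, 1, 1)

    def test_exhaustive_confusion_oracle_length_six(self):
        """All 2^6 x 2^6 binary label/score combinations against a literal
        per-element confusion count and a pairwise AUROC oracle."""
        for y_bits in itertools.product([0, 1], repeat=6):
            for s_bits in itertools.product([0, 1], repeat=6):
                calls = [1 if s >= 0.5 else 0 for s in s_bits]
                tp, fp, tn, fn = confusion_counts(y_bits, calls)
                m = compute_metrics(list(y_bits), [float(s) for s in s_bits])
                assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)
                expected_auc = pairwise_auroc(y_bits, s_bits)
                if expected_auc is None:
                    assert m.auroc is None
                else:
                    assert m.auroc == pytest.approx(expected_auc)

    def test_inverted_scores_flip_auroc(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 30).tolist()
        y[0], y[1] = 0, 1
        s = rng.random(30)  # tie-free almost surely
        a = compute_metrics(y, s).auroc
        b = compute_metrics(y, 1 - s).auroc
        assert a + b == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0.5])


class TestCrossValidate:
    def test_strong_signal_gb_accuracy(self):
        m, labels = signal_fixture(seed=2)
        genes = sorted(labels.positives) + sorted(labels.negatives)[:60]
        cv = cross_validate(ModelSpec("GB", seed=0, tuning="none"), m, genes,
                            m.feature_ids, labels, k=10, seed=0)
        assert cv.means["accuracy"] >= 0.95

    def test_shuffled_labels_auroc_near_half(self):
        m, labels = signal_fixture(seed=3)
        rng = np.random.default_rng(1)
        genes = sorted(labels.universe)
        fake_pos = rng.choice(genes, size=60, replace=False)
        shuffled = LabelSet.from_iterables(fake_pos, genes)
        train = sorted(fake_pos) + sorted(set(genes) - set(fake_pos))[:60]
        cv = cross_validate(ModelSpec("LR", seed=0, tuning="none"), m, train,
                            m.feature_ids, shuffled, k=10, seed=0)
        assert 0.35 <= cv.means["auroc"] <= 0.65

    def test_fold_count_and_ranges(self):
        m, labels = separable_fixture()
        cv = cross_validate(ModelSpec("LR", tuning="none"), m, m.gene_ids,
                            m.feature_ids, labels, k=5, seed=0)
        assert len(cv.per_fold) == 5
        assert ((cv.per_fold >= 0) & (cv.per_fold <= 1)).all().all()

    def test_too_few_samples(self):
        m, labels = separable_fixture(n=8)
        with pytest.raises(ValueError):
            cross_validate(ModelSpec("LR", tuning="none"), m, m.gene_ids,
                           m.feature_ids, labels, k=10)


class TestEnsembleCVTable:
    def _cv(self, model_type, acc):
        import pandas as pd

        per_fold = pd.DataFrame({k: [acc] for k in CVMetrics.METRICS})
        means = {k: acc for k in CVMetrics.METRICS}
        sds = {k: 0.0 for k in CVMetrics.METRICS}
        return CVMetrics(model_type, 10, per_fold, means, sds)

    def test_single_set_table_equals_metrics(self):
        t = ensemble_cv_table({"GB": [self._cv("GB", 0.9)]})
        assert t.loc["GB", "accuracy_mean"] == pytest.approx(0.9)

    def test_mean_of_two_sets(self):
        t = ensemble_cv_table({"GB": [self._cv("GB", 0.8), self._cv("GB", 0.9)]})
        assert t.loc["GB", "accuracy_mean"] == pytest.approx(0.85)

    def test_rows_are_model_types_sorted(self):
        t = ensemble_cv_table({mt: [self._cv(mt, 0.5)] for mt in MODEL_TYPES})
        assert list(t.index) == sorted(MODEL_TYPES)


class TestRankFeatures:
    def _records(self, n_records=3, seed=0):
        m, labels = signal_fixture(seed=seed, n_sig=8)
        spec = ModelSpec("GB", seed=seed, tuning="none")
        recs = [
            tune_and_train(spec, m, m.gene_ids, m.feature_ids, labels, set_index=i)
            for i in range(n_records)
        ]
        return m, labels, recs

    def test_identical_records_average_equals_each(self):
        m, _, recs = self._records()
        ranked, _ = rank_features(recs, m.feature_family, top_k=5)
        single, _ = rank_features(recs[:1], m.feature_family, top_k=5)
        assert list(ranked["feature_id"]) == list(single["feature_id"])
        np.testing.assert_allclose(ranked["mean_importance"], single["mean_importance"])

    def test_family_counts_sum_to_top_k(self):
        m, _, recs = self._records()
        _, fam = rank_features(recs, m.feature_family, top_k=5)
        for _, sub in fam.groupby("model_index"):
            assert sub["count"].sum() == 5

    def test_planted_signal_dominates_ranking(self):
        cfg = syn.SyntheticConfig(
            seed=4, n_genes=400, n_positives=80,
            families=(syn.FamilyConfig("famA", 60, 0.05, 20),),
            signal_rate=0.7,
        )
        m, labels = syn.generate_feature_matrix(cfg)
        spec = ModelSpec("GB", seed=1, tuning="none")
        recs = [tune_and_train(spec, m, m.gene_ids, m.feature_ids, labels)]
        ranked, _ = rank_features(recs, m.feature_family, top_k=10)
        sig = set(syn.signal_feature_ids(cfg))
        frac = np.mean([f in sig for f in ranked["feature_id"]])
        assert frac >= 0.8

    def test_model_without_importances_excluded(self):
        m, labels, recs = self._records()
        lr = tune_and_train(ModelSpec("LR", tuning="none"), m, m.gene_ids,
                            m.feature_ids, labels)
        ranked_with, _ = rank_features(recs + [lr], m.feature_family, top_k=5)
        ranked_without, _ = rank_features(recs, m.feature_family, top_k=5)
        assert list(ranked_with["feature_id"]) == list(ranked_without["feature_id"])

    def test_no_importances_at_all_is_error(self):
        m, labels, _ = self._records()
        lr = tune_and_train(ModelSpec("LR", tuning="none"), m, m.gene_ids,
                            m.feature_ids, labels)
        with pytest.raises(ValueError):
            rank_features([lr], m.feature_family)
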