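"""Linear SVM LOOCV: grid search, decision pooling, and the seven metrics."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from gliosom import SVMConfig, compute_metrics, loocv_classify, two_step_grid_search
from gliosom.classify import pairwise_auc
from gliosom.features import LabelRatioFeatureTable


def _table_from_logratios(log_ratios, genotype, ages=None):
    log_ratios = np.asarray(log_ratios, dtype=float)
    ratios = np.clip(10.0**log_ratios - 1e-2, 0.0, 100.0)
    n = log_ratios.shape[1]
    return LabelRatioFeatureTable(
        ratios=ratios,
        log_ratios=log_ratios,
        subject_ids=tuple(f"s{i}" for i in range(n)),
        genotype=np.asarray(genotype),
        age=np.asarray(ages if ages is not None else np.full(n, 50.0), dtype=float),
    )


def _separable_table(n_per_class=6, gap=1.5, seed=0):
    rng = np.random.default_rng(seed)
    wt = rng.normal(gap, 0.1, (4, n_per_class))
    mut = rng.normal(0.0, 0.1, (4, n_per_class))
    X = np.clip(np.hstack([wt, mut]), -2.0, 2.0)
    geno = ["wildtype"] * n_per_class + ["mutant"] * n_per_class
    return _table_from_logratios(X, geno)


class TestPairwiseAuc:
    def test_perfect_separation(self):
        truth = np.array(["wildtype", "wildtype", "mutant", "mutant"])
        assert pairwise_auc(np.array([0.9, 0.6, 0.4, 0.1]), truth, "wildtype") == 1.0

    def test_half_concordant_pairs(self):
        # positives (0.9, 0.1), negatives (0.4, 0.6): 2 of 4 pairs concordant
        truth = np.array(["wildtype", "wildtype", "mutant", "mutant"])
        assert pairwise_auc(np.array([0.9, 0.1, 0.4, 0.6]), truth, "wildtype") == 0.5

    def test_matches_brute_force_and_sklearn(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 50))
            scores = rng.normal(size=n).round(1)  # rounding forces ties
            truth = np.where(rng.random(n) < 0.5, "wildtype", "mutant")
            if len(np.unique(truth)) < 2:
                continue
            # independent oracle: explicit double loop with half-credit ties
            pos = scores[truth == "wildtype"]
            neg = scores[truth != "wildtype"]
            conc = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
            expected = conc / (len(pos) * len(neg))
            got = pairwise_auc(scores, truth, "wildtype")
            assert np.isclose(got, expected)
            assert np.isclose(got, roc_auc_score(truth == "wildtype", scores))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=20)
        truth = np.array(["wildtype"] * 10 + ["mutant"] * 10)
        a = pairwise_auc(scores, truth, "wildtype")
        b = pairwise_auc(np.exp(3 * scores), truth, "wildtype")
        assert np.isclose(a, b)


class TestComputeMetrics:
    def test_confusion_arithmetic(self):
        # TP=3, FP=1, FN=1, TN=5
        truth = np.array(["w"] * 4 + ["m"] * 6)
        preds = np.array(["w", "w", "w", "m", "w", "m", "m", "m", "m", "m"])
        dv = np.linspace(1, -1, 10)
        m, confusion = compute_metrics(dv, preds, truth, "w", return_confusion=True)
        assert confusion == {"TP": 3, "FP": 1, "FN": 1, "TN": 5}
        assert m["precision"] == 0.75
        assert m["recall"] == 0.75
        assert m["f1"] == 0.75
        assert m["accuracy"] == 0.8
        assert m["recall"] == m["sensitivity"]

    def test_undefined_metrics_are_nan_not_zero(self):
        truth = np.array(["w", "w", "m", "m"])
        preds = np.array(["m", "m", "m", "m"])  # nothing predicted positive
        m = compute_metrics(np.array([0.1, 0.2, -0.1, -0.2]), preds, truth, "w")
        assert np.isnan(m["precision"])
        assert m["sensitivity"] == 0.0

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros(3), np.array(["w"] * 3), np.array(["w"] * 3), "w")


class TestTwoStepGridSearch:
    def test_single_candidate_coarse_grid(self):
        table = _separable_table()
        config = SVMConfig(coarse_grid=(1.0,), seed=0)
        best = two_step_grid_search(table.log_ratios.T, table.genotype, config)
        assert 0.25 <= best <= 4.0  # within the fine span of the only candidate

    def test_fine_winner_within_span_of_coarse(self):
        table = _separable_table(seed=3)
        config = SVMConfig(seed=0)
        best = two_step_grid_search(table.log_ratios.T, table.genotype, config)
        coarse = sorted(config.coarse_grid)
        nearest = min(coarse, key=lambda c: abs(np.log(c) - np.log(best)))
        assert best <= nearest * config.fine_span * 1.0001
        assert best >= nearest / config.fine_span * 0.9999

    def test_separable_data_reaches_perfect_inner_cv(self):
        table = _separable_table(n_per_class=8, seed=1)
        config = SVMConfig(seed=2)
        X, y = table.log_ratios.T, table.genotype
        best = two_step_grid_search(X, y, config)
        from gliosom.classify import _cv_accuracy, _inner_folds

        folds = _inner_folds(np.asarray(y), config.inner_cv_folds, config.seed)
        assert _cv_accuracy(X, np.asarray(y), best, folds) == 1.0

    def test_single_class_training_rejected(self):
        config = SVMConfig(seed=0)
        with pytest.raises(ValueError, match="single class"):
            two_step_grid_search(np.random.rand(4, 2), ["w"] * 4, config)


class TestLoocv:
    def test_separable_classes_classified_perfectly(self):
        table = _separable_table(n_per_class=6)
        report = loocv_classify(table, SVMConfig(seed=0))
        assert report.metrics["accuracy"] == 1.0
        assert report.metrics["auc"] == 1.0

    def test_confusion_counts_sum_to_n(self, table_k8, svm_config):
        report = loocv_classify(table_k8, svm_config)
        assert sum(report.confusion.values()) == table_k8.n_subjects
        assert len(report.chosen_C) == table_k8.n_subjects  # one outer fit each

    def test_label_permutation_gives_chance_auc(self):
        rng = np.random.default_rng(7)
        aucs = []
        for perm_seed in range(5):
            X = np.clip(rng.normal(0.0, 0.5, (4, 16)), -2, 2)
            geno = np.array(["wildtype"] * 8 + ["mutant"] * 8)
            np.random.default_rng(perm_seed).shuffle(geno)
            if len(np.unique(geno)) < 2 or min(np.sum(geno == "wildtype"), np.sum(geno == "mutant")) < 2:
                continue
            table = _table_from_logratios(X, geno)
            aucs.append(loocv_classify(table, SVMConfig(seed=0)).metrics["auc"])
        assert 0.2 <= np.mean(aucs) <= 0.8  # Monte-Carlo band around 0.5

    def test_positive_class_flip_negates_decisions(self):
        table = _separable_table()
        a = loocv_classify(table, SVMConfig(seed=0, positive_class="wildtype"))
        b = loocv_classify(table, SVMConfig(seed=0, positive_class="mutant"))
        assert np.allclose(a.decision_values, -np.asarray(b.decision_values))
        # negating scores and swapping the positive group preserves AUC
        assert np.isclose(a.metrics["auc"], b.metrics["auc"])

    def test_age_feature_rescues_imageless_signal(self):
        # features carry no signal; age separates the classes completely
        rng = np.random.default_rng(3)
        X = np.clip(rng.normal(0.0, 0.3, (4, 12)), -2, 2)
        geno = ["wildtype"] * 6 + ["mutant"] * 6
        ages = np.array([70.0] * 6 + [35.0] * 6)
        table = _table_from_logratios(X, geno, ages)
        without = loocv_classify(table, SVMConfig(seed=0, include_age=False))
        with_age = loocv_classify(table, SVMConfig(seed=0, include_age=True))
        assert with_age.metrics["auc"] > without.metrics["auc"]
        assert with_age.metrics["auc"] >= 0.9

    def test_degenerate_table_warns(self):
        X = np.zeros((3, 8))
        table = _table_from_logratios(X, ["wildtype"] * 4 + ["mutant"] * 4)
        report = loocv_classify(table, SVMConfig(seed=0))
        assert any("degenerate" in w for w in report.warnings)

    def test_report_json_is_deterministic(self, table_k8, svm_config):
        a = loocv_classify(table_k8, svm_config).to_json()
        b = loocv_classify(table_k8, svm_config).to_json()
        assert a == b
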