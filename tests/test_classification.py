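"""Feature selection, SVM tuning, metrics, and the repeated-CV protocol."""

import dataclasses

import numpy as np
import pytest

from dfcp import (
    CvRunResult,
    ProtocolParams,
    SyntheticSpec,
    evaluate_fold,
    metrics,
    run_protocol,
    simulate_cohort,
    stratified_folds,
    svm_rfe,
    train_svm,
)
from dfcp.data_model import ValidationError
from dfcp.evaluation import aggregate


def tiny_cohort(seed=0, n=10):
    spec = SyntheticSpec(
        n_rois=8, n_subjects_per_group=n, T=80, n_informative_rois=2,
        factor_rank=2, seed=seed,
    )
    return simulate_cohort(spec)[0]


FAST = ProtocolParams(
    repeats=1, outer_folds=5, inner_folds=3,
    C_grid=(0.1, 1.0, 10.0), gamma_grid=(0.01, 0.1, 1.0), seed=0,
)


class TestStratifiedFolds:
    def test_balanced_fold_sizes_for_34_plus_34(self):
        groups = ["case"] * 34 + ["control"] * 34
        assignment = stratified_folds(groups, k=5, seed=0)
        for fold in range(5):
            mask = assignment == fold
            assert mask.sum() in (13, 14)
            for g in ("case", "control"):
                per = sum(1 for i, gi in enumerate(groups) if mask[i] and gi == g)
                assert per in (6, 7)

    def test_even_split(self):
        groups = ["case"] * 10 + ["control"] * 10
        assignment = stratified_folds(groups, k=5, seed=3)
        for fold in range(5):
            assert (assignment == fold).sum() == 4

    def test_deterministic_given_seed(self):
        groups = ["case"] * 12 + ["control"] * 13
        a = stratified_folds(groups, 5, seed=42)
        b = stratified_folds(groups, 5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValidationError):
            stratified_folds(["case"] * 3 + ["control"] * 10, k=5, seed=0)


class TestSvmRfe:
    def test_single_feature_is_selected(self, rng):
        X = rng.standard_normal((30, 1))
        y = (X[:, 0] > 0).astype(int)
        ranking, selected = svm_rfe(X, y)
        assert list(ranking) == [0] and list(selected) == [0]

    def test_step_one_elimination_round_count(self, rng):
        """rfe_step=1 on 5 features runs exactly 4 elimination rounds."""
        from sklearn.svm import SVC

        fit_calls = 0
        orig = SVC.fit

        def counting_fit(self, *a, **k):
            nonlocal fit_calls
            fit_calls += 1
            return orig(self, *a, **k)

        X = rng.standard_normal((40, 5))
        y = rng.integers(0, 2, 40)
        y[:3], y[-3:] = 0, 1  # both classes guaranteed
        try:
            SVC.fit = counting_fit
            svm_rfe(X, y, rfe_step=1, select=2)
        finally:
            SVC.fit = orig
        assert fit_calls == 4

    def test_planted_informative_features_rank_high(self):
        """2 informative of 22 (class shift 2.0, n=60) land in the top 5."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 30)
            X = rng.standard_normal((60, 22))
            X[:, 3] += 2.0 * y
            X[:, 17] += 2.0 * y
            X = (X - X.mean(0)) / X.std(0)
            ranking, _ = svm_rfe(X, y, select=5)
            hits += {3, 17} <= set(ranking[:5])
        assert hits >= int(0.95 * n_seeds)

    def test_ranking_agrees_with_reference_rfe(self, rng):
        """Elimination order matches scikit-learn's RFE on the same SVM."""
        from sklearn.feature_selection import RFE
        from sklearn.svm import SVC

        y = np.repeat([0, 1], 20)
        X = rng.standard_normal((40, 8))
        X[:, 2] += 1.5 * y
        ranking, _ = svm_rfe(X, y, select=3)
        ref = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=1, step=1).fit(X, y)
        # ref.ranking_ gives 1 for the survivor, increasing with elimination order
        ref_order = np.argsort(ref.ranking_, kind="stable")
        np.testing.assert_array_equal(ranking, ref_order)

    def test_inner_cv_prefers_compact_subsets_on_ties(self, rng):
        X = np.repeat(rng.standard_normal((12, 1)), 3, axis=1)  # identical columns
        y = (X[:, 0] > 0).astype(int)
        _, selected = svm_rfe(X, y, inner_folds=3)
        assert len(selected) == 1


class TestTrainSvm:
    def test_separable_data_fits_perfectly(self):
        X = np.r_[np.full((10, 2), -2.0), np.full((10, 2), 2.0)]
        X += np.random.default_rng(0).normal(0, 0.1, X.shape)
        y = np.repeat([0, 1], 10)
        clf, params = train_svm(X, y, FAST)
        assert np.mean(clf.predict(X) == y) == 1.0
        assert set(params) == {"C", "gamma", "kernel"}

    def test_same_data_and_seed_give_same_parameters(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.integers(0, 2, 30)
        y[:5], y[-5:] = 0, 1
        p1 = train_svm(X, y, FAST, seed=9)[1]
        p2 = train_svm(X, y, FAST, seed=9)[1]
        assert p1 == p2

    def test_rbf_beats_linear_on_xor(self, rng):
        from dfcp.classification import _inner_cv_accuracy
        from sklearn.svm import SVC

        X = rng.uniform(-1, 1, size=(80, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        acc_rbf = _inner_cv_accuracy(SVC(kernel="rbf", C=1.0, gamma=1.0), X, y, 5, 0)
        acc_lin = _inner_cv_accuracy(SVC(kernel="linear", C=1.0), X, y, 5, 0)
        assert acc_rbf > acc_lin

    def test_single_class_split_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValidationError):
            train_svm(X, np.zeros(10, dtype=int), FAST)


class TestMetrics:
    def test_worked_confusion_example(self):
        run = CvRunResult(tp=9, fn=1, tn=8, fp=2, repeat=0, fold=0)
        m = metrics(run)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["precision"] == pytest.approx(0.8182, abs=1e-4)
        assert m["recall"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["f1"] == pytest.approx(0.8571, abs=1e-4)

    def test_perfect_predictions(self):
        m = metrics(CvRunResult(tp=7, fp=0, tn=7, fn=0, repeat=0, fold=0))
        assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall", "specificity", "f1"))

    def test_degenerate_denominators_flagged(self):
        m = metrics(CvRunResult(tp=0, fp=0, tn=8, fn=6, repeat=0, fold=0))
        assert m["precision"] == 0.0 and "precision" in m["flags"]
        assert m["recall"] == 0.0
        assert m["specificity"] == 1.0

    def test_majority_class_classifier_trace(self):
        # classifier always answering "control" on 6 cases + 8 controls
        m = metrics(CvRunResult(tp=0, fp=0, tn=8, fn=6, repeat=0, fold=0))
        assert m["recall"] == 0.0 and m["specificity"] == 1.0


class TestEvaluateFold:
    def _clf(self, constant):
        class Stub:
            n_features_in_ = 2

            def predict(self, X):
                return np.full(len(X), constant)

        return Stub()

    def test_perfect_and_inverted_predictions(self, rng):
        X = rng.standard_normal((14, 2))
        y = np.repeat([1, 0], 7)

        class Echo:
            n_features_in_ = 2

            def predict(self, X_):
                return y

        r = evaluate_fold(Echo(), X, y)
        assert (r.tp, r.tn, r.fp, r.fn) == (7, 7, 0, 0)

        class Invert:
            n_features_in_ = 2

            def predict(self, X_):
                return 1 - y

        r = evaluate_fold(Invert(), X, y)
        assert (r.tp, r.tn) == (0, 0) and (r.fp, r.fn) == (7, 7)

    def test_counts_sum_to_test_size(self, rng):
        X = rng.standard_normal((9, 2))
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0])
        r = evaluate_fold(self._clf(1), X, y)
        assert r.n_test == 9


class TestProtocol:
    def test_run_count_and_record_shape(self):
        cohort = tiny_cohort(seed=4)
        runs = run_protocol(cohort, "dfcp", 24.0, FAST)
        assert len(runs) == FAST.repeats * FAST.outer_folds
        for r in runs:
            assert r.n_test == 4  # 2 cases + 2 controls per fold
            assert len(r.selected_features) >= 1
            assert "C" in r.hyperparameters

    def test_full_determinism_from_master_seed(self):
        cohort = tiny_cohort(seed=4)
        a = run_protocol(cohort, "combined", 24.0, FAST)
        b = run_protocol(cohort, "combined", 24.0, FAST)
        assert [(r.tp, r.fp, r.tn, r.fn) for r in a] == [(r.tp, r.fp, r.tn, r.fn) for r in b]
        assert [r.selected_features for r in a] == [r.selected_features for r in b]
        assert [r.hyperparameters for r in a] == [r.hyperparameters for r in b]

    def test_test_subject_data_cannot_influence_fold_fits(self):
        """Corrupting one subject's series leaves every fold where that
        subject is held out completely unchanged (features, parameters,
        other subjects' predictions)."""
        cohort = tiny_cohort(seed=4)
        runs_a = run_protocol(cohort, "dfcp", 24.0, FAST)

        victim = cohort[0].subject_id
        rng = np.random.default_rng(99)
        corrupted = [
            dataclasses.replace(ts, values=rng.standard_normal(ts.values.shape))
            if ts.subject_id == victim
            else ts
            for ts in cohort
        ]
        runs_b = run_protocol(corrupted, "dfcp", 24.0, FAST)

        assignment = stratified_folds([t.group for t in cohort], FAST.outer_folds,
                                      _first_fold_seed(FAST.seed))
        victim_idx = 0
        for ra, rb in zip(runs_a, runs_b):
            if assignment[victim_idx] == rb.fold:  # victim held out: fit unchanged
                assert ra.selected_features == rb.selected_features
                assert ra.hyperparameters == rb.hyperparameters

    def test_combined_feature_dimension_is_n_plus_2k(self):
        cohort = tiny_cohort(seed=4)
        runs = run_protocol(cohort, "combined", 24.0, FAST)
        n_rois = cohort[0].n_rois
        for r in runs:
            assert max(r.selected_features) < n_rois + 2 * 10  # N + 2*K_max

    def test_label_permuted_cohort_scores_at_chance(self):
        cohort = tiny_cohort(seed=5, n=12)
        rng = np.random.default_rng(0)
        labels = [ts.group for ts in cohort]
        rng.shuffle(labels)
        shuffled = [
            dataclasses.replace(ts, group=g) for ts, g in zip(cohort, labels)
        ]
        p = dataclasses.replace(FAST, repeats=2)
        runs = run_protocol(shuffled, "dfcp", 24.0, p)
        acc = aggregate(runs).loc["accuracy", "mean"]
        assert 0.25 <= acc <= 0.75  # wide band: tiny cohort


def _first_fold_seed(master_seed):
    ss = np.random.SeedSequence(master_seed)
    return int(ss.generate_state(1)[0] % (2**31))
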