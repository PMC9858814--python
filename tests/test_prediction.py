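"""Cohort splitting, resampling/weighting, RF training and MAE reporting."""

import numpy as np
import pandas as pd
import pytest

from radigen.prediction import (
    DEFAULT_PARAMS,
    REDUCED_GRID,
    PreprocessPlan,
    RfGrid,
    compute_sample_weights,
    oversample_bins,
    report_mae,
    select_top_features,
    split_cohort,
    train_and_evaluate,
)

RNG = np.random.default_rng(61)


def make_cohort(n=120, n_feats=8, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_feats))
    y = 0.8 * X[:, 0] + noise * rng.normal(size=n)
    feats = pd.DataFrame(
        X, index=[f"P{i:03d}" for i in range(n)],
        columns=[f"f{i:02d}" for i in range(n_feats)],
    )
    return feats, pd.Series(y, index=feats.index, name="es")


class TestSplitCohort:
    def test_174_splits_139_35(self):
        train, test = split_cohort([f"P{i}" for i in range(174)], seed=1)
        assert len(train) == 139 and len(test) == 35

    def test_deterministic_and_disjoint(self):
        ids = [f"P{i}" for i in range(50)]
        a = split_cohort(ids, seed=7)
        b = split_cohort(ids, seed=7)
        assert a == b
        assert set(a[0]).isdisjoint(a[1])
        assert sorted(a[0] + a[1]) == sorted(ids)

    def test_n10_gives_8_2(self):
        train, test = split_cohort(list(range(10)), seed=0)
        assert len(train) == 8 and len(test) == 2


class TestOversampleBins:
    def test_balanced_input_is_identity(self):
        targets = np.repeat(np.linspace(0, 1, 10), 3)
        idx = oversample_bins(targets, seed=0)
        np.testing.assert_array_equal(idx, np.arange(30))

    def test_two_bins_8_and_2(self):
        targets = np.array([0.0] * 8 + [1.0] * 2)
        idx = oversample_bins(targets, n_bins=2, seed=4)
        assert len(idx) == 16
        bins = (targets[idx] > 0.5).sum()
        assert bins == 8  # upsampled minority bin
        assert set(np.arange(10)).issubset(set(idx))

    def test_same_seed_same_multiset(self):
        targets = RNG.normal(size=40)
        a = oversample_bins(targets, seed=3)
        b = oversample_bins(targets, seed=3)
        np.testing.assert_array_equal(a, b)


class TestSampleWeights:
    def test_uniform_bins_unit_weights(self):
        targets = np.repeat(np.linspace(0, 1, 10), 5)
        np.testing.assert_allclose(compute_sample_weights(targets), 1.0)

    def test_9_1_ratio(self):
        targets = np.array([0.0] * 9 + [1.0])
        w = compute_sample_weights(targets, n_bins=2)
        assert w.mean() == pytest.approx(1.0)
        assert w[-1] / w[0] == pytest.approx(9.0)

    def test_positive_mean_one_property(self):
        for _ in range(100):
            targets = RNG.normal(size=RNG.integers(12, 60))
            if len(np.unique(targets)) < 2:
                continue
            w = compute_sample_weights(targets)
            assert np.all(w > 0)
            assert w.mean() == pytest.approx(1.0)


class TestSelectTopFeatures:
    def test_dominant_feature_first(self):
        imp = pd.DataFrame(
            {"a": [0.6, 0.7, 0.5], "b": [0.2, 0.1, 0.3], "c": [0.2, 0.2, 0.2]}
        )
        assert select_top_features(imp)[0] == "a"

    def test_tie_broken_alphabetically(self):
        imp = pd.DataFrame({"zeta": [0.5, 0.5], "alpha": [0.5, 0.5]})
        assert select_top_features(imp) == ["alpha", "zeta"]

    def test_matches_sort_oracle(self):
        names = [f"f{i:02d}" for i in range(30)]
        imp = pd.DataFrame(RNG.random((5, 30)), columns=names)
        top = select_top_features(imp)
        oracle = sorted(names, key=lambda f: (-imp[f].mean(), f))[:15]
        assert top == oracle


class TestReportMae:
    def test_exact_prediction_zero(self):
        assert report_mae([0.1, -0.4], [0.1, -0.4]) == 0.0

    def test_hand_arithmetic(self):
        assert report_mae([0.0, 0.0], [0.2, -0.2]) == pytest.approx(20.0)

    def test_matches_naive_loop(self):
        y = RNG.normal(size=50)
        yhat = RNG.normal(size=50)
        naive = sum(abs(a - b) for a, b in zip(y, yhat)) / 50 * 100
        assert report_mae(y, yhat) == pytest.approx(naive, rel=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            report_mae([], [])


class TestTrainAndEvaluate:
    def test_linear_target_beats_mean_baseline(self):
        feats, y = make_cohort(noise=0.0, seed=1)
        report = train_and_evaluate(feats, y, seed=1)
        assert report.internal_test_mae < 0.2 * report.baseline_test_mae

    def test_permuted_target_near_baseline(self):
        feats, y = make_cohort(noise=0.0, seed=2)
        y_perm = pd.Series(
            np.random.default_rng(3).permutation(y.to_numpy()), index=y.index
        )
        report = train_and_evaluate(feats, y_perm, seed=2)
        assert report.internal_test_mae <= 1.35 * report.baseline_test_mae

    def test_plan_passthrough_and_report_shape(self):
        feats, y = make_cohort(noise=0.3, seed=4)
        plan = PreprocessPlan(zscore=True, oversample_bins=True,
                              sample_weights=True)
        report = train_and_evaluate(feats, y, plan=plan, seed=4)
        assert report.plan == plan
        assert report.cv_mae_ci[0] <= report.cv_mae_mean <= report.cv_mae_ci[1]
        assert len(report.top_features) == min(15, feats.shape[1])
        assert report.params == DEFAULT_PARAMS

    def test_tuned_grid_values_recorded(self):
        feats, y = make_cohort(n=60, noise=0.5, seed=5)
        plan = PreprocessPlan(tune_hyperparams=True)
        small = RfGrid(n_estimators=(30,), criterion=("squared_error",),
                       max_depth=(2, None), max_samples=(None,),
                       max_features=(1.0,))
        report = train_and_evaluate(feats, y, plan=plan, grid=small, seed=5)
        assert report.params["n_estimators"] == 30
        assert report.params["max_depth"] in (2, None)

    def test_reproducible_given_seed(self):
        feats, y = make_cohort(noise=0.4, seed=6)
        r1 = train_and_evaluate(feats, y, seed=9)
        r2 = train_and_evaluate(feats, y, seed=9)
        assert r1.cv_fold_maes == r2.cv_fold_maes
        assert r1.internal_test_mae == r2.internal_test_mae

    def test_full_grid_matches_stated_values(self):
        grid = RfGrid()
        assert grid.n_estimators == (30, 50, 100, 250, 500, 1000, 2000)
        assert grid.criterion == ("absolute_error", "squared_error", "poisson")
        assert grid.max_depth == (2, 4, 6, 8, 10, None)
        assert grid.max_samples == (0.2, 0.4, 0.6, 0.8, None)
        assert grid.max_features == (0.2, 0.4, 0.6, 0.8, 1.0)


class TestLeakageGuard:
    def test_training_artifacts_ignore_test_targets(self):
        """Corrupting test-set targets must not change anything fit on train."""
        feats, y = make_cohort(noise=0.3, seed=8)
        train_ids, test_ids = split_cohort(feats.index, seed=8)
        y_bad = y.copy()
        y_bad.loc[test_ids] = 1e6
        r1 = train_and_evaluate(
            feats.loc[train_ids], y.loc[train_ids],
            test_features=feats.loc[test_ids], test_es=y.loc[test_ids],
            plan=PreprocessPlan(zscore=True, top15_only=True), seed=8,
        )
        r2 = train_and_evaluate(
            feats.loc[train_ids], y_bad.loc[train_ids],
            test_features=feats.loc[test_ids], test_es=y_bad.loc[test_ids],
            plan=PreprocessPlan(zscore=True, top15_only=True), seed=8,
        )
        assert r1.cv_fold_maes == r2.cv_fold_maes
        assert [f for f, _ in r1.top_features] == [f for f, _ in r2.top_features]
        assert r1.internal_test_mae != r2.internal_test_mae
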