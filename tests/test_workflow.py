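"""Evaluation protocol: splits, folds, CV selection, metrics, task runners."""

import numpy as np
import pandas as pd
import pytest

from svispec import (
    SpectraDataset,
    compute_metrics,
    cross_validate,
    make_folds,
    run_task,
    split_train_test,
)
from svispec.workflow import (
    StratificationError,
    TaskConfigurationError,
    UndefinedMetricError,
)


class TestSplit:
    def test_two_to_one_ratio(self):
        plan = split_train_test(180, seed=0)
        assert len(plan.train_idx) == 120 and len(plan.test_idx) == 60

    def test_smallest_case(self):
        plan = split_train_test(3, seed=1, strata=["a", "a", "a"])
        assert len(plan.train_idx) == 2 and len(plan.test_idx) == 1

    def test_partition_and_determinism(self):
        a = split_train_test(55, seed=7, strata=np.repeat(np.arange(11), 5))
        b = split_train_test(55, seed=7, strata=np.repeat(np.arange(11), 5))
        assert np.array_equal(a.train_idx, b.train_idx)
        union = np.sort(np.concatenate([a.train_idx, a.test_idx]))
        assert np.array_equal(union, np.arange(55))

    def test_stratified_keeps_every_class_in_both_halves(self):
        strata = np.repeat([f"B{i}" for i in range(15)], 12)
        plan = split_train_test(180, seed=3, strata=strata)
        for half in (plan.train_idx, plan.test_idx):
            assert set(strata[half]) == set(strata)

    def test_tiny_stratum_rejected(self):
        with pytest.raises(StratificationError):
            split_train_test(4, seed=0, strata=["a", "a", "a", "b"])


class TestFolds:
    def test_even_partition_120_by_10(self):
        folds = make_folds(120, 10, seed=0)
        assert all(len(f) == 12 for f in folds)
        assert np.array_equal(np.sort(np.concatenate(folds)), np.arange(120))

    def test_stratified_folds_partition(self):
        strata = np.repeat(list("abcd"), 10)
        folds = make_folds(40, 10, seed=1, strata=strata)
        assert np.array_equal(np.sort(np.concatenate(folds)), np.arange(40))

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, 6, seed=0)


class TestMetrics:
    def test_hand_computed_regression_metrics(self):
        met = compute_metrics([1, 2, 3], [1, 2, 4], "regression")
        assert met["rmse"] == pytest.approx(0.57735, abs=1e-4)
        assert met["mae"] == pytest.approx(1 / 3)
        assert met["r2"] == pytest.approx(0.5)

    def test_perfect_predictions(self):
        met = compute_metrics([1.0, 2.0], [1.0, 2.0], "regression")
        assert (met["rmse"], met["mae"], met["r2"]) == (0.0, 0.0, 1.0)
        cls = compute_metrics(["a", "b"], ["a", "b"], "classification")
        assert cls["accuracy"] == 1.0

    def test_accuracy_three_of_four(self):
        met = compute_metrics(list("aabb"), list("aaba"), "classification")
        assert met["accuracy"] == 0.75

    def test_confusion_rows_sum_to_class_counts(self):
        met = compute_metrics(list("aabbb"), list("ababa"), "classification")
        conf = np.array(met["confusion"])
        assert conf.sum(axis=1).tolist() == [2, 3]

    def test_rmse_at_least_mae(self, rng):
        for _ in range(20):
            y = rng.normal(size=9)
            p = rng.normal(size=9)
            met = compute_metrics(y, p, "regression")
            assert met["rmse"] >= met["mae"] >= 0.0

    def test_constant_truth_r2_undefined(self):
        with pytest.raises(UndefinedMetricError):
            compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0], "regression")


class TestCrossValidate:
    def test_single_candidate_selected(self, rng):
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6)
        cv = cross_validate(X, y, "plsr", grid=[2], k=5, seed=0)
        assert cv.selected == {"n_components": 2}

    def test_selects_enough_latent_directions(self, rng):
        # three informative orthogonal latent directions
        T = rng.normal(size=(60, 3))
        load = rng.normal(size=(3, 12))
        X = T @ load + 0.01 * rng.normal(size=(60, 12))
        y = T @ np.array([1.0, -2.0, 1.5])
        cv = cross_validate(X, y, "plsr", grid=list(range(1, 11)), k=10, seed=0)
        assert cv.selected["n_components"] >= 3

    def test_out_of_fold_predictions_cover_every_row_once(self, rng):
        X = rng.normal(size=(25, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=25)
        cv = cross_validate(X, y, "plsr", grid=[1, 2], k=5, seed=2)
        assert np.isfinite(cv.table["rmse"]).all()  # pooled over all rows

    def test_fold_count_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_validate(rng.normal(size=(5, 2)), rng.normal(size=5),
                           "plsr", grid=[1], k=6)


class TestRunTask:
    def test_regression_task_end_to_end(self, tiny_task5_zero_noise):
        rep = run_task(5, tiny_task5_zero_noise, "plsr", seed=0)
        assert rep.kind == "regression"
        assert rep.n_train + rep.n_test == 55
        assert rep.test_metrics["r2"] > 0.99

    def test_classification_task_end_to_end(self, tiny_task1_zero_noise):
        rep = run_task(1, tiny_task1_zero_noise, "plsda", seed=0)
        assert rep.kind == "classification"
        conf = np.array(rep.test_metrics["confusion"])
        assert conf.sum() == rep.n_test
        assert conf.sum(axis=1).tolist() == [4] * 15  # stratified test counts

    def test_fat_content_recovered_at_default_noise(self):
        """The simulator's monotone fat-to-colour link makes certified fat
        content recoverable by K-ELM under the default noise model."""
        import svispec as sv
        ds = sv.simulate_task_spectra(2, seed=1, noise=sv.NoiseModel(seed=1),
                                      roi_size=12)
        rep = run_task(2, ds, "kelm", seed=1)
        assert rep.test_metrics["r2"] >= 0.95

    def test_label_model_mismatch_rejected(self, tiny_task5_zero_noise,
                                           tiny_task1_zero_noise):
        with pytest.raises(TaskConfigurationError):
            run_task(5, tiny_task5_zero_noise, "plsda", seed=0)
        with pytest.raises(TaskConfigurationError):
            run_task(1, tiny_task1_zero_noise, "plsr", seed=0)

    def test_end_to_end_determinism(self, tiny_task5_zero_noise):
        a = run_task(5, tiny_task5_zero_noise, "kelm", seed=4).to_dict()
        b = run_task(5, tiny_task5_zero_noise, "kelm", seed=4).to_dict()
        assert a == b

    def test_no_leakage_from_test_rows(self, tiny_task5_zero_noise):
        """Corrupting the held-out rows must not change normalization,
        CV selection or the fitted model."""
        ds = tiny_task5_zero_noise
        plan = split_train_test(ds.n_samples, seed=6,
                                strata=ds.meta["level"].to_numpy())
        corrupted = SpectraDataset(X=ds.X.copy(), meta=ds.meta.copy())
        corrupted.X[plan.test_idx] += 1000.0

        rep_a, model_a, norm_a = run_task(5, ds, "plsr", seed=6, return_model=True)
        rep_b, model_b, norm_b = run_task(5, corrupted, "plsr", seed=6,
                                          return_model=True)
        assert rep_a.selected == rep_b.selected
        assert rep_a.cv_metrics == rep_b.cv_metrics
        assert np.array_equal(norm_a.mins_, norm_b.mins_)
        assert np.allclose(model_a.coefficients(), model_b.coefficients())

    def test_paper_compat_mode_leaks_by_design(self, tiny_task5_zero_noise):
        ds = tiny_task5_zero_noise
        plan = split_train_test(ds.n_samples, seed=6,
                                strata=ds.meta["level"].to_numpy())
        corrupted = SpectraDataset(X=ds.X.copy(), meta=ds.meta.copy())
        corrupted.X[plan.test_idx] += 1000.0
        _, _, norm_a = run_task(5, ds, "plsr", seed=6, paper_compat=True,
                                return_model=True)
        _, _, norm_b = run_task(5, corrupted, "plsr", seed=6, paper_compat=True,
                                return_model=True)
        assert not np.array_equal(norm_a.maxs_, norm_b.maxs_)
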