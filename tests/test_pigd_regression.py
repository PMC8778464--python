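import math

import numpy as np
import pytest

from pigdsense.pigd_regression import (
    ReductionSpec,
    SvrSpec,
    correlation_filter,
    default_grid,
    fit_predict_svr,
    metrics,
    nested_loso_optimize,
    normalize,
    pca_reduce,
)


def _linear_cohort(n=20, n_features=20, n_informative=5, noise=0.05, seed=0):
    """Severity-linked feature matrix with a linear generative law."""
    rng = np.random.default_rng(seed)
    target = np.linspace(0.0, 20.0, n)
    features = rng.standard_normal((n, n_features))
    for j in range(n_informative):
        slope = 1.0 if j % 2 == 0 else -1.0
        features[:, j] = slope * target / 20.0 + noise * rng.standard_normal(n)
    return features, target


class TestCorrelationFilter:
    def test_feature_equal_to_target_ranked_first(self):
        rng = np.random.default_rng(0)
        target = np.arange(10.0)
        features = np.column_stack([rng.standard_normal(10), target.copy()])
        kept, r = correlation_filter(features, target)
        assert kept[0] == 1
        assert r[1] == pytest.approx(1.0)

    def test_negated_target_retained(self):
        target = np.arange(10.0)
        features = (-target)[:, None]
        kept, r = correlation_filter(features, target)
        assert kept == [0]
        assert r[0] == pytest.approx(-1.0)

    def test_moderate_signal_kept_noise_dropped(self):
        rng = np.random.default_rng(1)
        n = 200
        target = rng.standard_normal(n)
        sigma = math.sqrt(1 / 0.6**2 - 1)  # gives r ~= 0.6
        signal = target + sigma * rng.standard_normal(n)
        noise = rng.standard_normal(n)
        features = np.column_stack([signal, noise])
        kept, r = correlation_filter(features, target)
        # oracle: direct correlation computation
        assert r[0] == pytest.approx(np.corrcoef(signal, target)[0, 1], abs=1e-12)
        assert kept == [0]

    def test_zero_variance_feature_dropped(self):
        target = np.arange(10.0)
        features = np.column_stack([np.ones(10), target])
        kept, r = correlation_filter(features, target)
        assert 0 not in kept
        assert r[0] == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        target = rng.standard_normal(50)
        features = rng.standard_normal((50, 8))
        kept1, r1 = correlation_filter(features, target, r_floor=0.0)
        kept2, r2 = correlation_filter(3.0 * features - 7.0, target, r_floor=0.0)
        assert kept1 == kept2
        np.testing.assert_allclose(r1, r2, atol=1e-12)


class TestPcaReduce:
    def test_line_explains_everything(self):
        t = np.linspace(0, 1, 10)
        data = np.column_stack([t, 2 * t, -t])
        train, test, var = pca_reduce(data, data, 1)
        assert var[0] == pytest.approx(1.0)

    def test_projection_has_diagonal_covariance(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((30, 6))
        train, _, _ = pca_reduce(data, data, 4)
        cov = np.cov(train.T)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-9

    def test_all_components_capture_total_variance(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((20, 5))
        _, _, var = pca_reduce(data, data, 5)
        assert var.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca_reduce(np.zeros((5, 3)), np.zeros((2, 3)), 5)


class TestNormalize:
    def test_minmax_arithmetic(self):
        train = np.array([[1.0], [2.0], [3.0]])
        s_train, _, _, _ = normalize(train, train, np.array([0.0, 1.0, 2.0]))
        np.testing.assert_allclose(s_train.ravel(), [0.0, 0.5, 1.0], atol=1e-12)

    def test_target_inverse_round_trip(self):
        target = np.array([2.0, 7.0, 13.0, 20.0])
        train = np.arange(8.0).reshape(4, 2)
        _, _, y_scaled, scaler = normalize(train, train, target)
        np.testing.assert_allclose(scaler.inverse(y_scaled), target, atol=1e-9)
        assert y_scaled.min() == 0.0 and y_scaled.max() == 1.0

    def test_test_row_equal_to_train_row(self):
        rng = np.random.default_rng(0)
        train = rng.standard_normal((10, 3))
        _, s_test, _, _ = normalize(train, train[[4]], np.arange(10.0))
        s_train, _, _, _ = normalize(train, train, np.arange(10.0))
        np.testing.assert_allclose(s_test[0], s_train[4], atol=1e-12)

    def test_out_of_range_test_values_soft_clipped(self):
        train = np.array([[0.0], [1.0]])
        _, s_test, _, _ = normalize(train, np.array([[100.0], [-100.0]]), np.array([0.0, 1.0]))
        assert s_test.max() <= 1.5 and s_test.min() >= -0.5


class TestFitPredictSvr:
    def test_linear_noiseless_within_epsilon(self):
        x = np.linspace(0, 1, 20)[:, None]
        y = 2 * x.ravel() + 1
        spec = SvrSpec("linear", 1.0, 1000.0, epsilon=0.01)
        pred = fit_predict_svr(x, y, x, spec)
        assert np.max(np.abs(pred - y)) <= 0.01 + 1e-3

    def test_duplicated_rows_do_not_change_linear_fit(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((15, 3))
        y = x @ np.array([1.0, -2.0, 0.5])
        y = y - y.mean()
        spec = SvrSpec("linear", 1.0, 100.0, epsilon=0.01)
        base = fit_predict_svr(x, y, x, spec)
        doubled = fit_predict_svr(np.vstack([x, x]), np.concatenate([y, y]), x, spec)
        np.testing.assert_allclose(doubled, base, atol=5e-2)

    def test_wide_gaussian_approaches_mean_predictor(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, (20, 4))
        y = rng.standard_normal(20)
        y = y - y.mean()
        spec = SvrSpec("gaussian", 1000.0, 1.0, epsilon=0.01)
        pred = fit_predict_svr(x, y, x, spec)
        # the kernel is ~constant, so the fit collapses to a single level
        # (an epsilon-insensitive central value of y, near its mean)
        assert pred.max() - pred.min() < 1e-3
        assert abs(pred.mean() - y.mean()) < 0.5 * y.std()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SvrSpec("sigmoid", 1.0, 1.0)
        with pytest.raises(ValueError):
            SvrSpec("linear", 1.0, 1e6)


class TestNestedLoso:
    def test_fold_and_fit_counts(self):
        features, target = _linear_cohort(n=6, n_features=6)
        grid = default_grid(kernels=("linear", "gaussian"), log_values=(0.1, 10.0))
        g = len(grid)
        result = nested_loso_optimize(
            features, target, [f"S{i}" for i in range(6)],
            ReductionSpec("correlation_rank", 3), grid,
        )
        assert result.n_outer_folds == 6
        assert result.n_inner_fits == 6 * 5 * g

    def test_linear_law_recovers_linear_kernel(self):
        features, target = _linear_cohort(n=20, seed=4)
        grid = default_grid(kernels=("linear", "gaussian"), log_values=(0.01, 1.0, 100.0))
        result = nested_loso_optimize(
            features, target, [f"S{i}" for i in range(20)],
            ReductionSpec("correlation_rank", 5), grid,
        )
        kernels = [s.kernel for s in result.chosen_specs]
        assert kernels.count("linear") / len(kernels) >= 0.8
        assert result.r >= 0.95

    def test_grid_order_is_tie_break_order(self):
        grid = default_grid()
        kernel_rank = {k: i for i, k in enumerate(("linear", "quadratic", "cubic", "gaussian"))}
        keys = [(kernel_rank[s.kernel], s.box_constraint, s.kernel_scale) for s in grid]
        assert keys == sorted(keys)

    def test_leakage_safety_held_out_row_cannot_steer_selection(self):
        features, target = _linear_cohort(n=8, seed=2)
        grid = default_grid(kernels=("linear",), log_values=(0.1, 10.0))
        spec = ReductionSpec("correlation_rank", 3)
        base = nested_loso_optimize(features, target, [f"S{i}" for i in range(8)], spec, grid)
        perturbed = features.copy()
        perturbed[3] += 100.0  # held-out features must not affect fold 3's pipeline
        alt = nested_loso_optimize(perturbed, target, [f"S{i}" for i in range(8)], spec, grid)
        assert alt.chosen_specs[3] == base.chosen_specs[3]
        assert alt.inner_rmse[3] == pytest.approx(base.inner_rmse[3], abs=1e-12)

    def test_noise_degrades_r(self):
        grid = default_grid(kernels=("linear",), log_values=(0.1, 10.0))
        medians = []
        for noise in (0.05, 0.5, 2.0):
            rs = []
            for seed in range(3):
                features, target = _linear_cohort(n=12, noise=noise, seed=seed)
                res = nested_loso_optimize(
                    features, target, [f"S{i}" for i in range(12)],
                    ReductionSpec("correlation_rank", 3), grid,
                )
                rs.append(res.r)
            medians.append(np.median(rs))
        assert medians[0] > medians[1] > medians[2]

    def test_paper_mode_runs(self):
        features, target = _linear_cohort(n=8, seed=0)
        grid = default_grid(kernels=("linear",), log_values=(1.0,))
        res = nested_loso_optimize(
            features, target, [f"S{i}" for i in range(8)],
            ReductionSpec("pca", 3), grid, paper_mode=True,
        )
        assert res.n_outer_folds == 8

    def test_too_few_subjects(self):
        features, target = _linear_cohort(n=3)
        with pytest.raises(ValueError):
            nested_loso_optimize(features[:3], target[:3], ["a", "b", "c"], ReductionSpec())


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([0.1, 0.4, 0.9])
        r, rmse, mae = metrics(y, y)
        assert r == pytest.approx(1.0)
        assert rmse == 0.0 and mae == 0.0

    def test_constant_offset(self):
        y = np.array([0.1, 0.4, 0.9])
        r, rmse, mae = metrics(y, y + 0.1)
        assert r == pytest.approx(1.0)
        assert rmse == pytest.approx(0.1)
        assert mae == pytest.approx(0.1)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        y_true = rng.standard_normal(1000)
        y_pred = rng.standard_normal(1000)
        r, rmse, mae = metrics(y_true, y_pred)
        # independent re-implementation, plain loops over the definitions
        n = len(y_true)
        my, mp = sum(y_true) / n, sum(y_pred) / n
        cov = sum((a - my) * (b - mp) for a, b in zip(y_true, y_pred)) / n
        sy = math.sqrt(sum((a - my) ** 2 for a in y_true) / n)
        sp = math.sqrt(sum((b - mp) ** 2 for b in y_pred) / n)
        r_ref = cov / (sy * sp)
        rmse_ref = math.sqrt(sum((b - a) ** 2 for a, b in zip(y_true, y_pred)) / n)
        mae_ref = sum(abs(b - a) for a, b in zip(y_true, y_pred)) / n
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert rmse == pytest.approx(rmse_ref, abs=1e-12)
        assert mae == pytest.approx(mae_ref, abs=1e-12)

    def test_zero_variance_reports_zero_r(self):
        r, rmse, mae = metrics(np.array([1.0, 1.0]), np.array([1.0, 2.0]))
        assert r == 0.0
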