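"""pFSFS (p-value filter + forward SFS + QDA) and the LASSO pipeline."""

import numpy as np
import pytest
from scipy import stats

from cmcsel.selectors import (
    LassoFit,
    forward_sfs_qda,
    lambda_max,
    lasso_objective,
    lasso_path_select,
    lasso_select,
    pfsfs_select,
    pvalue_filter,
    rank_and_refit_svm,
)


def _two_class(n=40, p=10, seed=0, sep_cols=(), sep=1.0, noise=0.01):
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, noise, size=(2 * n, p))
    y = np.repeat([1, 2], n)
    for c in sep_cols:
        X[y == 2, c] += sep
    return X, y


class TestPvalueFilter:
    def test_identical_column_removed(self):
        X, y = _two_class(sep_cols=(0,), sep=1.0)
        X[:, 3] = 0.42  # constant in both classes
        surv, p = pvalue_filter(X, y)
        assert 3 not in surv
        assert p[3] == 1.0

    def test_separated_column_retained_matching_t_statistic(self):
        X, y = _two_class(n=20, sep_cols=(2,), sep=1.0, noise=0.01)
        surv, p = pvalue_filter(X, y)
        assert 2 in surv
        _, p_direct = stats.ttest_ind(X[y == 1, 2], X[y == 2, 2], equal_var=False)
        assert p[2] == pytest.approx(p_direct)
        assert p[2] < 1e-10

    def test_alpha_one_keeps_everything(self):
        X, y = _two_class()
        surv, _ = pvalue_filter(X, y, alpha=1.0)
        assert len(surv) == X.shape[1]

    def test_survivors_monotone_in_alpha(self):
        X, y = _two_class(sep_cols=(0, 1), sep=0.02)
        prev = set()
        for alpha in (0.001, 0.05, 0.5, 1.0):
            surv, _ = pvalue_filter(X, y, alpha)
            assert prev <= set(surv.tolist())
            prev = set(surv.tolist())


class TestForwardSfs:
    def test_perfect_separator_selected_first_with_zero_trace(self):
        X, y = _two_class(sep_cols=(4,), sep=5.0, noise=0.05)
        cols, trace = forward_sfs_qda(X, y, np.arange(10), seed=0)
        assert cols[0] == 4
        assert trace[0] == 0.0

    def test_shuffled_labels_halt_early_at_chance(self):
        X, y = _two_class(sep_cols=(0,), sep=3.0)
        rng = np.random.default_rng(1)
        ys = rng.permutation(y)
        cols, trace = forward_sfs_qda(X, ys, np.arange(10), seed=0)
        assert len(cols) <= 3
        if trace:
            assert trace[-1] == pytest.approx(0.5, abs=0.15)

    def test_trace_is_non_increasing(self):
        X, y = _two_class(sep_cols=(0, 5), sep=0.02, noise=0.02, seed=3)
        _, trace = forward_sfs_qda(X, y, np.arange(10), seed=0)
        assert all(a >= b for a, b in zip(trace, trace[1:]))

    def test_empty_candidates_rejected(self):
        X, y = _two_class()
        with pytest.raises(ValueError):
            forward_sfs_qda(X, y, np.array([], dtype=int))


class TestLassoPath:
    def test_beta_zero_at_and_above_lambda_max(self):
        X, y = _two_class(n=20, p=5, sep_cols=(1,), sep=1.0)
        yy = (y == 2).astype(float)
        Xs = (X - X.mean(0)) / X.std(0)
        lmax = lambda_max(Xs, yy)
        fit = lasso_path_select(X, y, lambda_grid=np.array([2 * lmax, 1.01 * lmax]))
        assert np.all(fit.beta == 0.0)

    def test_orthonormal_design_matches_soft_threshold(self):
        from cmcsel.selectors import fit_lasso

        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.standard_normal((8, 4)))
        X = Q  # columns orthonormal, X^T X = I
        beta_true = np.array([2.0, -1.0, 0.5, 0.0])
        y = X @ beta_true
        n = len(y)
        for lam in (0.01, 0.05, 0.2):
            # subgradient condition gives beta_j = soft(x_j^T y, n * lam)
            b_ols = X.T @ y
            expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - n * lam, 0.0)
            _, beta = fit_lasso(X, y, lam, fit_intercept=False)
            np.testing.assert_allclose(beta, expected, atol=1e-6)

    def test_zero_lambda_recovers_least_squares(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 0.01 * rng.standard_normal(20)
        labels = (y > np.median(y)).astype(int) + 1
        yy = (labels == 2).astype(float)
        fit = lasso_path_select(X, labels, lambda_grid=np.array([0.0]))
        Xs = (X - X.mean(0)) / X.std(0)
        beta_ols, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(20), Xs]), yy, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols[1:], atol=1e-6)

    def test_objective_no_worse_than_null_model(self):
        X, y = _two_class(n=25, p=6, sep_cols=(0,), sep=1.0, seed=4)
        fit = lasso_path_select(X, y, seed=0)
        yy = (y == 2).astype(float)
        Xs = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
        at_fit = lasso_objective(Xs, yy, fit.beta0, fit.beta, fit.lambda_star)
        at_null = lasso_objective(Xs, yy, yy.mean(), np.zeros(6), fit.lambda_star)
        assert at_fit <= at_null + 1e-12

    def test_sparsity_non_increasing_along_default_path(self):
        X, y = _two_class(n=30, p=8, sep_cols=(0, 3), sep=0.5, seed=5)
        yy = (y == 2).astype(float)
        Xs = (X - X.mean(0)) / X.std(0)
        from sklearn.linear_model import lasso_path
        lmax = lambda_max(Xs, yy)
        grid = np.logspace(np.log10(lmax), np.log10(lmax * 1e-4), 30)
        _, coefs, _ = lasso_path(Xs, yy - yy.mean(), alphas=grid)
        nnz = (coefs != 0).sum(axis=0)  # grid is decreasing in lambda
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))

    def test_non_finite_values_rejected(self):
        X, y = _two_class()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            lasso_path_select(X, y)


class TestRankAndRefit:
    def _fit(self, beta, p):
        grid = np.array([0.1, 0.05])
        return LassoFit(
            lambda_star=0.05, beta0=0.0, beta=np.asarray(beta, dtype=float),
            lambda_grid=grid, cv_mse_curve=np.array([0.3, 0.2]),
            standardize_mean=np.zeros(p), standardize_scale=np.ones(p),
        )

    def test_zero_coefficients_discarded_and_ranked_by_magnitude(self):
        X, y = _two_class(n=20, p=3, sep_cols=(0,), sep=2.0)
        run = rank_and_refit_svm(X, y, self._fit([0.9, 0.0, -0.5], 3), seed=0)
        assert 1 not in run.selected_columns
        assert list(run.selected_columns) in ([0], [0, 2])

    def test_dominant_feature_needs_prefix_of_one(self):
        X, y = _two_class(n=25, p=4, sep_cols=(2,), sep=5.0, noise=0.05)
        run = rank_and_refit_svm(X, y, self._fit([0.0, 0.01, 1.0, 0.01], 4), seed=0)
        assert list(run.selected_columns) == [2]
        assert run.cv_mce == 0.0

    def test_tied_magnitudes_order_by_lower_column(self):
        X, y = _two_class(n=20, p=3, sep_cols=(0, 2), sep=1.0)
        beta = np.array([0.5, 0.0, -0.5])
        nz = np.flatnonzero(beta)
        order = nz[np.lexsort((nz, -np.abs(beta[nz])))]
        assert list(order) == [0, 2]

    def test_all_zero_beta_rejected(self):
        X, y = _two_class()
        with pytest.raises(RuntimeError, match="lambda"):
            rank_and_refit_svm(X, y, self._fit([0.0] * 10, 10), seed=0)


class TestPipelines:
    def test_both_pipelines_recover_planted_columns(self, planted_matrix):
        fm, planted = planted_matrix
        run_p = pfsfs_select(fm.values, fm.labels, seed=0)
        run_l = lasso_select(fm.values, fm.labels, seed=0)
        for run in (run_p, run_l):
            hits = set(run.selected_columns.tolist()) & set(planted)
            assert len(hits) >= 0.8 * min(len(planted), len(run.selected_columns))
            assert run.cv_mce <= 0.1
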