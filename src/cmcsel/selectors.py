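"""Comparator feature-selection pipelines: pFSFS and LASSO.

pFSFS: a per-feature two-sample p-value filter (Welch t-test, threshold
0.05) followed by forward sequential feature selection wrapped around a
quadratic discriminant analysis (QDA) classifier, scored by inner-CV mean
classification error (MCE).

LASSO: the L1-penalized least-squares path

    L = 1/(2N) * sum_i (y_i - b0 - x_i^T beta)^2 + lambda * ||beta||_1

on class labels coded {0, 1}, with lambda chosen by 5-fold CV at minimum
mean squared error; surviving features are ranked by |beta| and an RBF SVM
is refitted on prefixes of the ranking, keeping the prefix with minimum CV
MCE.  The coordinate-descent path itself is delegated to scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .results import SelectionRun

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
SFS_TOL = 1e-6


# ---------------------------------------------------------------- pFSFS ---

def pvalue_filter(values: np.ndarray, labels: np.ndarray, alpha: float = DEFAULT_ALPHA
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Columns surviving a per-feature Welch two-sample t-test at ``alpha``.

    Returns ``(surviving column indices, all p-values)``.  A column with
    zero variance in both classes has an undefined statistic; its p-value
    is set to 1 (removed) and logged.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("p-value filter requires exactly two classes")
    a, b = values[labels == classes[0]], values[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least two samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, equal_var=False)
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        logger.info("p-value filter: %d zero-variance columns set to p=1",
                    int(np.sum(degenerate)))
        p = np.where(degenerate, 1.0, p)
    return np.flatnonzero(p <= alpha), p


def _qda(reg: float = 1e-6) -> QuadraticDiscriminantAnalysis:
    return QuadraticDiscriminantAnalysis(reg_param=reg)


def _qda_fit(X: np.ndarray, y: np.ndarray) -> QuadraticDiscriminantAnalysis:
    """Fit QDA, escalating the covariance shrinkage on rank deficiency."""
    import warnings
    for reg in (1e-6, 1e-3, 1e-1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return _qda(reg).fit(X, y)
        except np.linalg.LinAlgError:
            logger.info("QDA covariance singular at reg=%g; increasing", reg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _qda(0.5).fit(X, y)


def _cv_mce(clf, X: np.ndarray, y: np.ndarray, folds, fit_data=None) -> float:
    """Mean CV error; ``fit_data(rows)`` may rebalance a fold's training part."""
    errs = []
    for tr, va in folds:
        Xt, yt = (X[tr], y[tr]) if fit_data is None else fit_data(tr)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # QDA collinearity warnings
            if isinstance(clf, QuadraticDiscriminantAnalysis):
                clf = _qda_fit(Xt, yt)
            else:
                clf.fit(Xt, yt)
            errs.append(np.mean(clf.predict(X[va]) != y[va]))
    return float(np.mean(errs))


def forward_sfs_qda(
    values: np.ndarray,
    labels: np.ndarray,
    candidates: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    tol: float = SFS_TOL,
    max_features: int | None = None,
    subject_ids: np.ndarray | None = None,
    balancer=None,
) -> tuple[np.ndarray, list[float]]:
    """Greedy forward selection with QDA, scored by inner-CV MCE.

    At each step the candidate whose addition minimizes the CV MCE is
    accepted if it improves the current MCE by more than ``tol``; otherwise
    selection stops.  Returns the selected columns in acceptance order and
    the (non-increasing) MCE trace over accepted steps.  ``balancer``
    (optional ``(values, labels, subject_ids) -> (values, labels)``) is
    applied to each fold's training part only.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    candidates = list(np.asarray(candidates, dtype=int))
    if not candidates:
        raise ValueError("no candidate columns for forward selection")
    folds = list(StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
                 .split(values, labels))
    balanced_folds = None
    if balancer is not None:
        sids = None if subject_ids is None else np.asarray(subject_ids)
        balanced_folds = [
            balancer(values[tr], labels[tr], None if sids is None else sids[tr])
            for tr, _ in folds
        ]

    selected: list[int] = []
    trace: list[float] = []
    current = np.inf
    while candidates and (max_features is None or len(selected) < max_features):
        scores = []
        for c in candidates:
            cols = selected + [c]
            if balanced_folds is None:
                scores.append(_cv_mce(_qda(), values[:, cols], labels, folds))
            else:
                errs = []
                for (tr, va), (Xb, yb) in zip(folds, balanced_folds):
                    q = _qda_fit(Xb[:, cols], yb)
                    errs.append(np.mean(q.predict(values[va][:, cols]) != labels[va]))
                scores.append(float(np.mean(errs)))
        best_i = int(np.argmin(scores))
        if current - scores[best_i] <= tol:
            break
        current = scores[best_i]
        selected.append(candidates.pop(best_i))
        trace.append(current)
    return np.asarray(selected, dtype=int), trace


def pfsfs_select(
    values: np.ndarray,
    labels: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    n_folds: int = 5,
    seed: int = 0,
    max_features: int | None = None,
    subject_ids: np.ndarray | None = None,
    balancer=None,
) -> SelectionRun:
    """p-value filter -> forward SFS -> QDA, as one selection run."""
    survivors, pvals = pvalue_filter(values, labels, alpha)
    if len(survivors) == 0:
        raise RuntimeError(f"no feature survives the p<= {alpha} filter")
    cols, trace = forward_sfs_qda(values, labels, survivors, n_folds, seed,
                                  max_features=max_features,
                                  subject_ids=subject_ids, balancer=balancer)
    if len(cols) == 0:  # no candidate improves over the empty model
        cols = survivors[:1]
        trace = [np.nan]
    Xf, yf = (values, labels) if balancer is None else balancer(values, labels, subject_ids)
    model = _qda_fit(Xf[:, cols], yf)
    return SelectionRun(
        algorithm="pfsfs",
        selected_columns=cols,
        params={"alpha": alpha, "n_candidates": int(len(survivors))},
        cv_mce=float(trace[-1]),
        model=model,
        extras={"mce_trace": [float(t) for t in trace]},
    )


# ---------------------------------------------------------------- LASSO ---

@dataclass
class LassoFit:
    """An L1 path fit: tuned penalty, coefficients, and the CV MSE curve."""

    lambda_star: float
    beta0: float
    beta: np.ndarray
    lambda_grid: np.ndarray
    cv_mse_curve: np.ndarray
    standardize_mean: np.ndarray
    standardize_scale: np.ndarray

    def __post_init__(self) -> None:
        if self.lambda_star < 0:
            raise ValueError("lambda must be nonnegative")
        i = int(np.argmin(self.cv_mse_curve))
        if not np.isclose(self.lambda_grid[i], self.lambda_star):
            raise ValueError("lambda_star must attain the minimum of cv_mse_curve")


def fit_lasso(X: np.ndarray, y: np.ndarray, lam: float,
              fit_intercept: bool = True) -> tuple[float, np.ndarray]:
    """Single L1 fit of the penalized objective at penalty ``lam``.

    Returns ``(beta0, beta)``.  ``lam = 0`` is the ordinary least-squares
    limit, solved directly.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam == 0.0:
        from sklearn.linear_model import LinearRegression
        model = LinearRegression(fit_intercept=fit_intercept).fit(X, y)
    else:
        model = Lasso(alpha=lam, fit_intercept=fit_intercept, max_iter=100_000,
                      tol=1e-10).fit(X, y)
    return float(np.atleast_1d(model.intercept_)[0] if fit_intercept else 0.0), \
        np.asarray(model.coef_)


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty with an all-zero solution: max_j |x_j^T (y - ybar)| / N."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / len(y))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def lasso_path_select(
    values: np.ndarray,
    labels: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 100,
) -> LassoFit:
    """Fit the L1 path, choose lambda by ``n_folds``-fold CV at minimum MSE.

    Class labels are coded {0, 1} as the numeric response; features are
    standardized on each training fold (and on the full split for the final
    fit).  The default grid is ``n_lambdas`` log-spaced penalties from
    lambda_max down to 1e-4 * lambda_max.
    """
    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("LASSO selection requires exactly two classes")
    y = (labels == classes[1]).astype(float)

    Xs_full, mu, sd = _standardize(X)
    if lambda_grid is None:
        lmax = lambda_max(Xs_full, y)
        lambda_grid = np.logspace(np.log10(lmax), np.log10(lmax * 1e-4), n_lambdas)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    folds = list(StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
                 .split(X, labels))
    sse = np.zeros(len(lambda_grid))
    n_val = 0
    # the coordinate-descent path needs strictly positive penalties; a zero
    # penalty in the grid is evaluated as ordinary least squares
    path_grid = np.maximum(lambda_grid, 1e-12)
    for tr, va in folds:
        Xt, mu_t, sd_t = _standardize(X[tr])
        Xv = (X[va] - mu_t) / sd_t
        yt = y[tr]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, _ = lasso_path(Xt, yt - yt.mean(), alphas=path_grid)
        pred = Xv @ coefs + yt.mean()  # (n_va, n_lambdas)
        sse += np.sum((pred - y[va][:, None]) ** 2, axis=0)
        n_val += len(va)
    cv_mse = sse / n_val

    i_star = int(np.argmin(cv_mse))
    lam = float(lambda_grid[i_star])
    beta0, beta = fit_lasso(Xs_full, y, lam)
    return LassoFit(
        lambda_star=lam,
        beta0=beta0,
        beta=beta,
        lambda_grid=lambda_grid,
        cv_mse_curve=cv_mse,
        standardize_mean=mu,
        standardize_scale=sd,
    )


def lasso_objective(X: np.ndarray, y: np.ndarray, beta0: float, beta: np.ndarray,
                    lam: float) -> float:
    """The penalized objective L evaluated at (beta0, beta)."""
    resid = y - beta0 - X @ beta
    return float(resid @ resid / (2 * len(y)) + lam * np.sum(np.abs(beta)))


def rank_and_refit_svm(
    values: np.ndarray,
    labels: np.ndarray,
    fit: LassoFit,
    n_folds: int = 5,
    seed: int = 0,
    svm_c_grid: tuple[float, ...] = (1.0, 10.0, 100.0),
    subject_ids: np.ndarray | None = None,
    balancer=None,
) -> SelectionRun:
    """Rank nonzero-|beta| features and refit an SVM on growing prefixes.

    Zero-coefficient features are discarded; the rest are ordered by |beta|
    descending (ties to the lower column index).  For each prefix length an
    RBF SVM (C tuned on a small grid) is scored by stratified CV MCE; the
    shortest prefix attaining the minimum MCE is returned.  ``balancer``
    is applied to each fold's training part only.
    """
    beta = np.asarray(fit.beta, dtype=float)
    nz = np.flatnonzero(beta != 0.0)
    if len(nz) == 0:
        raise RuntimeError("all LASSO coefficients are zero; decrease lambda")
    order = nz[np.lexsort((nz, -np.abs(beta[nz])))]  # |beta| desc, index asc

    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    folds = list(StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
                 .split(X, labels))
    balanced_folds = None
    if balancer is not None:
        sids = None if subject_ids is None else np.asarray(subject_ids)
        balanced_folds = [
            balancer(X[tr], labels[tr], None if sids is None else sids[tr])
            for tr, _ in folds
        ]

    def _prefix_mce(cols, C):
        errs = []
        for fi, (tr, va) in enumerate(folds):
            Xt, yt = (X[tr], labels[tr]) if balanced_folds is None else balanced_folds[fi]
            clf = SVC(kernel="rbf", C=C, gamma="scale").fit(Xt[:, cols], yt)
            errs.append(np.mean(clf.predict(X[va][:, cols]) != labels[va]))
        return float(np.mean(errs))

    curve = []
    best = (np.inf, None, None)  # (mce, prefix_len, C)
    for plen in range(1, len(order) + 1):
        cols = order[:plen]
        mces = [_prefix_mce(cols, C) for C in svm_c_grid]
        i = int(np.argmin(mces))
        if mces[i] < best[0] - 1e-12:
            best = (mces[i], plen, svm_c_grid[i])
        curve.append(float(mces[i]))
    mce, plen, C = best
    cols = order[:plen]
    Xf, yf = (X, labels) if balancer is None else balancer(X, labels, subject_ids)
    model = SVC(kernel="rbf", C=C, gamma="scale").fit(Xf[:, cols], yf)
    return SelectionRun(
        algorithm="lasso",
        selected_columns=np.asarray(cols, dtype=int),
        params={"lambda": fit.lambda_star, "svm_C": float(C), "n_nonzero": int(len(nz))},
        cv_mce=float(mce),
        model=model,
        extras={"mce_vs_prefix": [float(v) for v in curve],
                "cv_mse_curve": [float(v) for v in fit.cv_mse_curve]},
    )


def lasso_select(
    values: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    subject_ids: np.ndarray | None = None,
    balancer=None,
) -> SelectionRun:
    """LASSO path + |beta| ranking + incremental SVM refit, as one run.

    The penalty path is fitted on the (possibly balanced) full training
    split; the SVM prefix search applies ``balancer`` per fold.
    """
    if balancer is None:
        fit = lasso_path_select(values, labels, n_folds=n_folds, seed=seed)
    else:
        Xb, yb = balancer(values, labels, subject_ids)
        fit = lasso_path_select(Xb, yb, n_folds=n_folds, seed=seed)
    return rank_and_refit_svm(values, labels, fit, n_folds=n_folds, seed=seed,
                              subject_ids=subject_ids, balancer=balancer)
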