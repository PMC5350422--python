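"""Elastic-net variable selection and the EN-PLS model.

A whole-chromatogram design has thousands of collinear variables; most
carry no information about the bioactivity.  The elastic net minimises

    ||y - X b||^2 + lambda1 ||b||_1 + lambda2 ||b||^2

by cyclic coordinate descent, producing a sparse coefficient vector whose
support (the nonzero coordinates) names the retention-time points that
matter.  The L2 term gives the grouping effect — coefficients of highly
correlated variables (neighbouring points under one peak) are pulled
together, so whole peaks enter or leave the support as a unit.  The "naive"
elastic net is used without the (1 + lambda2) rescaling of coefficients:
only the support is consumed downstream, and support is invariant to that
rescaling.

EN-PLS then refits a NIPALS PLS model on the selected columns only, with
the component count chosen by leave-one-out cross-validation on the
restricted design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .pls import PLSRegressionNIPALS, loo_cv

__all__ = ["ENSelection", "ElasticNetSelector", "ENPLSRegressor",
           "fit_elastic_net", "lambda1_max", "default_lambda_grids",
           "tune_en", "fit_en_pls"]


@dataclass
class ENSelection:
    """Outcome of an elastic-net fit: coefficients, support, convergence."""

    lambda1: float
    lambda2: float
    beta: np.ndarray  # full-length, on the centred problem
    support: np.ndarray  # indices with beta != 0
    n_selected: int
    n_iter: int
    final_change: float
    converged: bool


def _center(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    return X - X.mean(axis=0), y - y.mean(), X.mean(axis=0), float(y.mean())


def lambda1_max(X, y) -> float:
    """Smallest L1 penalty that zeroes every coefficient: 2 max_j |x_j'(y - ybar)|."""
    Xc, yc, _, _ = _center(X, y)
    return float(2.0 * np.max(np.abs(Xc.T @ yc)))


class ElasticNetSelector(BaseEstimator):
    """Sparse variable selection by coordinate-descent elastic net.

    Parameters
    ----------
    lambda1, lambda2 : float
        L1 and L2 penalty weights in the objective
        ``||y - Xb||^2 + lambda1 ||b||_1 + lambda2 ||b||^2`` (X and y are
        centred internally; no intercept penalty).
    tol : float
        Convergence threshold on the maximum coordinate change per sweep.
    max_iter : int
        Maximum number of full-equivalent sweeps.

    Attributes
    ----------
    coef_ : ndarray
        Full-length coefficient vector.
    support_ : ndarray of int
        Indices of nonzero coefficients.
    n_selected_ : int
    n_iter_ : int, final_change_ : float, converged_ : bool
        Convergence diagnostics; non-convergence is reported, not raised.
    """

    def __init__(self, lambda1: float = 1.0, lambda2: float = 0.1,
                 tol: float = 1e-6, max_iter: int = 10_000):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, warm_start: np.ndarray | None = None):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalties must be >= 0")
        Xc, yc, x_mean, y_mean = _center(X, y)
        n, p = Xc.shape
        gram = Xc.T @ Xc
        corr = Xc.T @ yc
        diag = np.diag(gram).copy()
        beta = np.zeros(p) if warm_start is None else np.asarray(warm_start, dtype=float).copy()
        gb = gram @ beta if warm_start is not None and np.any(beta) else np.zeros(p)
        thresh = self.lambda1 / 2.0
        denom = diag + self.lambda2
        zero_cols = denom <= 0  # constant columns get (and keep) beta 0

        def sweep(active_idx) -> float:
            nonlocal gb
            max_change = 0.0
            for j in active_idx:
                bj = beta[j]
                r = corr[j] - gb[j] + diag[j] * bj
                new = np.sign(r) * max(abs(r) - thresh, 0.0) / denom[j]
                if new != bj:
                    delta = new - bj
                    beta[j] = new
                    gb += gram[:, j] * delta
                    change = abs(delta)
                    if change > max_change:
                        max_change = change
            return max_change

        all_idx = np.flatnonzero(~zero_cols)
        n_iter = 0
        change = np.inf
        converged = False
        while n_iter < self.max_iter:
            change = sweep(all_idx)
            n_iter += 1
            if change < self.tol:
                converged = True
                break
            # iterate the active set until it stabilises, then re-check all
            active = np.flatnonzero(beta != 0)
            while n_iter < self.max_iter and active.size:
                change = sweep(active)
                n_iter += 1
                if change < self.tol:
                    break
        self.x_mean_, self.y_mean_ = x_mean, y_mean
        self.coef_ = beta
        self.support_ = np.flatnonzero(beta)
        self.n_selected_ = int(self.support_.size)
        self.n_iter_ = n_iter
        self.final_change_ = float(change if np.isfinite(change) else 0.0)
        self.converged_ = converged
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]

    def kkt_residual(self, X, y) -> float:
        """Maximum violation of the elastic-net stationarity conditions.

        At a minimiser, active coordinates satisfy
        ``2 (Gb - c)_j + 2 lambda2 b_j + lambda1 sign(b_j) = 0`` and
        inactive ones ``|2 (c - Gb)_j| <= lambda1``.
        """
        Xc, yc, _, _ = _center(X, y)
        g = 2.0 * (Xc.T @ (Xc @ self.coef_) - Xc.T @ yc) + 2.0 * self.lambda2 * self.coef_
        active = self.coef_ != 0
        res_active = np.abs(g[active] + self.lambda1 * np.sign(self.coef_[active]))
        res_inactive = np.maximum(np.abs(g[~active]) - self.lambda1, 0.0)
        pieces = np.concatenate([res_active, res_inactive])
        return float(pieces.max()) if pieces.size else 0.0

    def selection(self) -> ENSelection:
        return ENSelection(lambda1=self.lambda1, lambda2=self.lambda2,
                           beta=self.coef_.copy(), support=self.support_.copy(),
                           n_selected=self.n_selected_, n_iter=self.n_iter_,
                           final_change=self.final_change_, converged=self.converged_)


def fit_elastic_net(X, y, lambda1: float, lambda2: float,
                    tol: float = 1e-6, max_iter: int = 10_000) -> ENSelection:
    sel = ElasticNetSelector(lambda1=lambda1, lambda2=lambda2,
                             tol=tol, max_iter=max_iter).fit(X, y)
    return sel.selection()


def default_lambda_grids(X, y, n_lambda1: int = 20):
    """Conventional grids: lambda2 in {0.01, 0.1, 1, 10}; lambda1 geometric
    over three decades down from the all-zero threshold."""
    l1max = lambda1_max(X, y)
    lambda1_grid = list(l1max * np.geomspace(1.0, 1e-3, n_lambda1))
    return lambda1_grid, [0.01, 0.1, 1.0, 10.0]


class ENPLSRegressor(BaseEstimator, RegressorMixin):
    """Elastic-net variable selection followed by PLS on the support.

    Parameters mirror :class:`ElasticNetSelector` plus ``max_components``
    for the downstream PLS (component count chosen by leave-one-out CV on
    the restricted design, capped by the support size).

    Attributes
    ----------
    selector_ : ElasticNetSelector
    support_ : ndarray of int
    pls_ : PLSRegressionNIPALS
        Fitted on the selected columns; ``variable_subset`` = support, so
        ``predict`` accepts full-grid matrices.
    n_components_ : int, rmsecv_ : ndarray
    """

    def __init__(self, lambda1: float = 1.0, lambda2: float = 0.1,
                 max_components: int = 15, tol: float = 1e-6,
                 max_iter: int = 10_000):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.max_components = max_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self.selector_ = ElasticNetSelector(
            lambda1=self.lambda1, lambda2=self.lambda2,
            tol=self.tol, max_iter=self.max_iter).fit(X, y)
        support = self.selector_.support_
        if support.size == 0:
            raise ValueError(
                "elastic net selected no variables; decrease lambda1 "
                f"(all-zero threshold is {lambda1_max(X, y):.4g})")
        self.support_ = support
        n = X.shape[0]
        cap = int(min(self.max_components, n - 2, support.size))
        if cap >= 1 and n >= 3:
            self.rmsecv_, a_opt = loo_cv(X, y, cap, variable_subset=support)
        else:
            self.rmsecv_, a_opt = np.array([np.nan]), 1
        self.n_components_ = a_opt
        self.pls_ = PLSRegressionNIPALS(n_components=a_opt,
                                        variable_subset=support).fit(X, y)
        self.coef_ = self.pls_.coef_
        self.intercept_ = self.pls_.intercept_
        return self

    def predict(self, X) -> np.ndarray:
        return self.pls_.predict(X)

    def full_coef(self, n_features: int) -> np.ndarray:
        return self.pls_.full_coef(n_features)


def fit_en_pls(X, y, lambda1: float, lambda2: float, max_components: int = 15,
               tol: float = 1e-6, max_iter: int = 10_000):
    """Fit EN-PLS; returns ``(ENSelection, fitted PLS model)``."""
    m = ENPLSRegressor(lambda1=lambda1, lambda2=lambda2,
                       max_components=max_components, tol=tol,
                       max_iter=max_iter).fit(X, y)
    return m.selector_.selection(), m.pls_


def _contiguous_folds(n: int, folds: int):
    """Contiguous block fold assignment over the given row order."""
    sizes = np.full(folds, n // folds)
    sizes[: n % folds] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [(int(bounds[k]), int(bounds[k + 1])) for k in range(folds)]


def tune_en(X_train, y_train, lambda1_grid, lambda2_grid, folds: int = 5,
            max_components: int = 10):
    """Pick elastic-net penalties by k-fold CV of the downstream EN-PLS fit.

    Folds are contiguous blocks of the given (Kennard-Stone-ordered) rows,
    so tuning is deterministic.  Best = minimal CV RMSE; ties go to the
    larger lambda1 (the sparser model).  Grid points where the net selects
    nothing on some fold are scored infinitely bad.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    if len(lambda1_grid) == 0 or len(lambda2_grid) == 0:
        raise ValueError("penalty grids must be non-empty")
    if any(v < 0 for v in list(lambda1_grid) + list(lambda2_grid)):
        raise ValueError("penalty grid values must be >= 0")
    n = X_train.shape[0]
    if not 2 <= folds <= n:
        raise ValueError(f"folds must be in [2, {n}]")
    fold_bounds = _contiguous_folds(n, folds)
    results = {}
    for lam2 in lambda2_grid:
        for lam1 in sorted(lambda1_grid, reverse=True):  # warm-startable order
            sq = 0.0
            ok = True
            for lo, hi in fold_bounds:
                mask = np.ones(n, dtype=bool)
                mask[lo:hi] = False
                try:
                    m = ENPLSRegressor(lambda1=lam1, lambda2=lam2,
                                       max_components=max_components).fit(
                        X_train[mask], y_train[mask])
                except ValueError:
                    ok = False
                    break
                pred = m.predict(X_train[lo:hi])
                sq += float(np.sum((pred - y_train[lo:hi]) ** 2))
            results[(lam1, lam2)] = np.sqrt(sq / n) if ok else np.inf
    best = min(results, key=lambda k: (results[k], -k[0]))
    return best[0], best[1], results
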