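"""NIPALS partial least squares regression for a single response.

PLS projects the (mean-centred) design onto a small number of latent
components that maximise covariance with the response, then regresses on
the component scores.  For a single response the NIPALS weight vector has
the closed form ``w = X_d' y_d / ||X_d' y_d||`` at each deflation round, so
fitting is deterministic — no iterative inner loop, no random start.

Variables are centred but not autoscaled by default: on a chromatographic
fingerprint every variable shares one unit (absorbance), and the regression
coefficients are read downstream as sensitivities on the raw intensity
scale.  Autoscaling is available behind a flag.

The estimator follows the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
composes with sklearn model selection; the plain functions ``fit_pls``,
``predict`` and ``loo_cv`` are thin wrappers.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["PLSRegressionNIPALS", "fit_pls", "predict", "loo_cv"]


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] != len(y):
        raise ValueError(f"X has {X.shape[0]} rows but y has {len(y)} values")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    return X, y


class PLSRegressionNIPALS(BaseEstimator, RegressorMixin):
    """Single-response PLS regression fit by NIPALS deflation.

    Parameters
    ----------
    n_components : int
        Number of latent components (>= 1).
    variable_subset : array-like of int, optional
        Column indices of the full design the model uses; ``fit`` and
        ``predict`` always receive the full-grid matrix and subset
        internally.  ``None`` uses every column.
    scale : bool
        If True, autoscale columns to unit variance before fitting
        (coefficients are reported back on the original scale).

    Attributes
    ----------
    x_mean_ : ndarray, y_mean_ : float
        Centering applied to the (subset of the) design and the response.
    x_weights_, x_loadings_ : ndarray of shape (n_used, n_components)
        NIPALS weights W and loadings P per component.
    y_loadings_ : ndarray of shape (n_components,)
        Response loadings q.
    coef_ : ndarray of shape (n_used,)
        Regression vector b on the original intensity scale.
    intercept_ : float
        The prediction is ``intercept_ + X[:, subset] @ coef_``.
    fitted_values_ : ndarray
        In-sample predictions stored at fit time.
    """

    def __init__(self, n_components: int = 2, variable_subset=None, scale: bool = False):
        self.n_components = n_components
        self.variable_subset = variable_subset
        self.scale = scale

    # -- internals -----------------------------------------------------
    def _subset(self, X: np.ndarray) -> np.ndarray:
        if self.variable_subset is None:
            return X
        idx = np.asarray(self.variable_subset, dtype=int)
        if idx.size == 0:
            raise ValueError("variable_subset is empty")
        if X.shape[1] <= idx.max():
            raise ValueError("X has fewer columns than variable_subset requires")
        return X[:, idx]

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        Xs = self._subset(X)
        n, p = Xs.shape
        a_max = min(n - 1, p)
        if not 1 <= self.n_components <= a_max:
            raise ValueError(
                f"n_components must be in [1, {a_max}] for a {n}x{p} design")
        if np.std(y) == 0:
            raise ValueError("degenerate input: y has zero variance")

        self.x_mean_ = Xs.mean(axis=0)
        self.y_mean_ = float(y.mean())
        if self.scale:
            sd = Xs.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            self.x_std_ = sd
        else:
            self.x_std_ = np.ones(p)
        Xd = (Xs - self.x_mean_) / self.x_std_
        yd = y - self.y_mean_

        A = self.n_components
        W = np.empty((p, A))
        P = np.empty((p, A))
        q = np.empty(A)
        for a in range(A):
            w = Xd.T @ yd
            norm = np.linalg.norm(w)
            if norm == 0:  # response fully deflated; stop early
                W, P, q, A = W[:, :a], P[:, :a], q[:a], a
                break
            w /= norm
            t = Xd @ w
            tt = float(t @ t)
            if tt == 0:
                W, P, q, A = W[:, :a], P[:, :a], q[:a], a
                break
            pvec = Xd.T @ t / tt
            qa = float(yd @ t) / tt
            Xd = Xd - np.outer(t, pvec)
            yd = yd - qa * t
            W[:, a], P[:, a], q[a] = w, pvec, qa
        if A == 0:
            raise ValueError("degenerate input: X carries no covariance with y")
        self.n_components_ = A
        self.x_weights_, self.x_loadings_, self.y_loadings_ = W, P, q
        self.coef_ = self._coef_for(A)
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        self.fitted_values_ = self.predict(X)
        return self

    def _coef_for(self, a: int) -> np.ndarray:
        """Regression vector using the first ``a`` components (original scale)."""
        W, P, q = self.x_weights_[:, :a], self.x_loadings_[:, :a], self.y_loadings_[:a]
        # b = W (P'W)^{-1} q ; P'W is unit upper triangular for NIPALS
        b = W @ np.linalg.solve(P.T @ W, q)
        return b / self.x_std_

    def coefficients_path(self) -> np.ndarray:
        """(n_used, n_components_) matrix: regression vector per component count."""
        return np.column_stack([self._coef_for(a) for a in range(1, self.n_components_ + 1)])

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        Xs = self._subset(X)
        if Xs.shape[1] != len(self.coef_):
            raise ValueError(
                f"X has {Xs.shape[1]} usable columns, model expects {len(self.coef_)}")
        return self.intercept_ + Xs @ self.coef_

    def full_coef(self, n_features: int) -> np.ndarray:
        """Regression vector embedded in the full-grid coordinate system."""
        if self.variable_subset is None:
            if n_features != len(self.coef_):
                raise ValueError("n_features does not match the fitted design")
            return self.coef_.copy()
        out = np.zeros(n_features)
        out[np.asarray(self.variable_subset, dtype=int)] = self.coef_
        return out


def fit_pls(X, y, n_components: int, variable_subset=None, scale: bool = False) -> PLSRegressionNIPALS:
    return PLSRegressionNIPALS(n_components=n_components,
                               variable_subset=variable_subset, scale=scale).fit(X, y)


def predict(model: PLSRegressionNIPALS, X) -> np.ndarray:
    return model.predict(X)


def loo_cv(X, y, max_components: int, variable_subset=None, scale: bool = False):
    """Leave-one-out RMSECV per component count and the optimal count.

    For each left-out sample one NIPALS model is fitted at the maximal
    order and evaluated at every component count via the per-component
    coefficient path, so the cost is n fits rather than n x A.  The optimum
    minimises RMSECV; ties go to the smaller count (parsimony).
    """
    X, y = _validate_xy(X, y)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out CV")
    p = X.shape[1] if variable_subset is None else len(np.asarray(variable_subset))
    a_cap = min(max_components, n - 2, p)
    if a_cap < 1:
        raise ValueError("max_components leaves no admissible component count")
    sq_err = np.zeros(a_cap)
    counts = np.zeros(a_cap, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        m = PLSRegressionNIPALS(n_components=a_cap, variable_subset=variable_subset,
                                scale=scale).fit(X[mask], y[mask])
        path = m.coefficients_path()  # may have fewer columns if deflation exhausted
        xs = m._subset(X[i][None, :])[0] - 0.0
        for a in range(path.shape[1]):
            b = path[:, a]
            pred = m.y_mean_ - float(m.x_mean_ @ b) + float(xs @ b)
            sq_err[a] += (pred - y[i]) ** 2
            counts[a] += 1
    valid = counts == n
    if not np.any(valid):
        raise ValueError("leave-one-out failed at every component count")
    rmsecv = np.full(a_cap, np.inf)
    rmsecv[valid] = np.sqrt(sq_err[valid] / n)
    # parsimony: smallest count whose RMSECV ties the minimum, where a tie
    # allows numerical noise (relative 1e-9 plus 1e-12 of the response scale)
    best = rmsecv.min()
    tie = best * (1 + 1e-9) + 1e-12 * float(np.sqrt(np.mean(y ** 2)))
    optimum = int(np.flatnonzero(rmsecv <= tie)[0]) + 1
    return rmsecv, optimum
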