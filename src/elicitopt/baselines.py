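"""Linear-regression comparison models: MLR, stepwise, OLSR, PCR, PLSR.

All five reduce to an intercept plus a coefficient vector on (a subset of)
the original input columns, so a single :class:`LinearModel` container
serves them all.  MLR and OLSR are the same ordinary-least-squares
estimator under two names (they are reported as separate rows in model
comparison tables, where their statistics coincide); stepwise selects
columns by bidirectional p-value search; PCR and PLSR regress on latent
components of the standardized inputs and back-transform the coefficients
to the original columns.

Main effects only — no interactions or polynomial terms — which is exactly
why these baselines underfit a curved dose-time response surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import LeaveOneOut

METHODS = ("MLR", "SR", "OLSR", "PCR", "PLSR")


@dataclass
class LinearModel:
    """Intercept + coefficients on retained original-scale columns."""

    intercept: float
    coefficients: np.ndarray
    retained_columns: tuple[int, ...]
    method: str
    components: int | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.retained_columns),):
            raise ValueError("coefficients must align with retained_columns")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not self.retained_columns:
            return np.full(X.shape[0], self.intercept)
        return self.intercept + X[:, list(self.retained_columns)] @ self.coefficients


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, d) aligned with y")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    return X, y


def _ols(X, y):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def fit_mlr(X, y) -> LinearModel:
    """Ordinary least squares on all columns with intercept."""
    X, y = _check_Xy(X, y)
    n, d = X.shape
    if n <= d + 1:
        raise ValueError(f"need n > d + 1 (n={n}, d={d})")
    rank = np.linalg.matrix_rank(np.hstack([np.ones((n, 1)), X]))
    if rank < d + 1:
        raise np.linalg.LinAlgError("design matrix is rank deficient (collinear columns)")
    res = _ols(X, y)
    return LinearModel(intercept=float(res.params[0]),
                       coefficients=res.params[1:],
                       retained_columns=tuple(range(d)), method="MLR")


def fit_olsr(X, y) -> LinearModel:
    """Same estimator as :func:`fit_mlr`, tagged OLSR for reporting."""
    m = fit_mlr(X, y)
    m.method = "OLSR"
    return m


def fit_stepwise(X, y, alpha_enter: float = 0.05,
                 alpha_remove: float = 0.10) -> LinearModel:
    """Bidirectional p-value stepwise selection, then OLS on the survivors.

    Starting from the intercept-only model, repeatedly add the candidate
    column with the smallest partial-t p-value below ``alpha_enter``, then
    drop any included column whose p-value exceeds ``alpha_remove``.
    ``alpha_enter <= alpha_remove`` guarantees termination.  An empty
    selection (pure-noise response) yields the intercept-only model.
    """
    X, y = _check_Xy(X, y)
    if alpha_enter > alpha_remove:
        raise ValueError("alpha_enter must not exceed alpha_remove")
    n, d = X.shape
    if n <= d + 1:
        raise ValueError(f"need n > d + 1 (n={n}, d={d})")
    included: list[int] = []
    while True:
        changed = False
        candidates = [j for j in range(d) if j not in included]
        if candidates:
            pvals = {}
            for j in candidates:
                cols = included + [j]
                res = _ols(X[:, cols], y)
                pvals[j] = res.pvalues[-1]
            best = min(pvals, key=pvals.get)
            if pvals[best] < alpha_enter:
                included.append(best)
                changed = True
        if included:
            res = _ols(X[:, included], y)
            worst_i = int(np.argmax(res.pvalues[1:]))
            if res.pvalues[1 + worst_i] > alpha_remove:
                included.pop(worst_i)
                changed = True
        if not changed:
            break
    if not included:
        return LinearModel(intercept=float(y.mean()), coefficients=np.array([]),
                           retained_columns=(), method="SR")
    included = sorted(included)
    res = _ols(X[:, included], y)
    return LinearModel(intercept=float(res.params[0]),
                       coefficients=res.params[1:],
                       retained_columns=tuple(included), method="SR")


def _standardize(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def default_pcr_components(X, explained: float = 0.95) -> int:
    """Smallest k whose principal components explain >= ``explained``."""
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    sv = np.linalg.svd(Xs - Xs.mean(axis=0), compute_uv=False)
    var = sv ** 2
    frac = np.cumsum(var) / var.sum()
    return int(np.searchsorted(frac, explained) + 1)


def fit_pcr(X, y, k: int | None = None) -> LinearModel:
    """Principal-component regression on standardized columns.

    Projects onto the top-``k`` principal components, regresses the
    response on the scores, and folds the loadings and standardization
    back into an intercept + original-column coefficient vector.  With
    ``k = d`` this is an exact re-parameterization of MLR.
    """
    X, y = _check_Xy(X, y)
    d = X.shape[1]
    if k is None:
        k = default_pcr_components(X)
    if not 1 <= k <= d:
        raise ValueError(f"components k must be in [1, {d}], got {k}")
    Xs, mean, sd = _standardize(X)   # Xs has column means 0
    _, _, Vt = np.linalg.svd(Xs, full_matrices=False)
    V = Vt[:k].T                      # (d, k) loadings
    res = _ols(Xs @ V, y)
    beta_std = V @ res.params[1:]     # coefficients on standardized columns
    # yhat = b0 + (X - mean)/sd @ beta_std
    intercept = float(res.params[0] - (mean / sd) @ beta_std)
    return LinearModel(intercept=intercept, coefficients=beta_std / sd,
                       retained_columns=tuple(range(d)), method="PCR",
                       components=k)


def default_plsr_components(X, y, k_max: int | None = None) -> int:
    """Component count minimizing leave-one-out RMSE (ties to fewer)."""
    X, y = _check_Xy(X, y)
    d = X.shape[1]
    k_max = d if k_max is None else min(k_max, d)
    best_k, best_err = 1, np.inf
    loo = LeaveOneOut()
    for k in range(1, k_max + 1):
        errs = []
        for tr, te in loo.split(X):
            pls = PLSRegression(n_components=k, scale=True)
            pls.fit(X[tr], y[tr])
            errs.append(float(pls.predict(X[te]).ravel()[0]) - y[te][0])
        err = float(np.sqrt(np.mean(np.square(errs))))
        if err < best_err - 1e-12:
            best_k, best_err = k, err
    return best_k


def fit_plsr(X, y, k: int | None = None) -> LinearModel:
    """Partial least squares (NIPALS) with back-transformed coefficients."""
    X, y = _check_Xy(X, y)
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    d = X.shape[1]
    if k is None:
        k = default_plsr_components(X, y)
    if not 1 <= k <= d:
        raise ValueError(f"components k must be in [1, {d}], got {k}")
    pls = PLSRegression(n_components=k, scale=True)
    pls.fit(X, y)
    # the PLS prediction is affine in X; recover intercept + coefficients
    # exactly by projecting the fitted map onto [1, X]
    yhat0 = pls.predict(X).ravel()
    b = np.linalg.lstsq(np.hstack([np.ones((X.shape[0], 1)), X]),
                        yhat0, rcond=None)[0]
    return LinearModel(intercept=float(b[0]), coefficients=b[1:],
                       retained_columns=tuple(range(d)), method="PLSR",
                       components=k)


def fit_all(X, y, stepwise_alphas=(0.05, 0.10), pcr_k: int | None = None,
            plsr_k: int | None = None) -> dict[str, LinearModel]:
    """All five baselines on one design matrix."""
    return {
        "MLR": fit_mlr(X, y),
        "SR": fit_stepwise(X, y, *stepwise_alphas),
        "PLSR": fit_plsr(X, y, plsr_k),
        "PCR": fit_pcr(X, y, pcr_k),
        "OLSR": fit_olsr(X, y),
    }
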