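"""Model evaluation criteria: RMSE, MAE, coefficient of determination, and
the overall-significance F-test p-value used in model comparison tables.

R-squared is computed as 1 - SSE/SST about the mean of the *actual*
values.  On held-out data this can be negative (the model predicts worse
than the training-set mean), and negative values are reported as-is rather
than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm


def _check_pair(y_est, y_act, min_n: int = 1):
    y_est = np.asarray(y_est, dtype=float).ravel()
    y_act = np.asarray(y_act, dtype=float).ravel()
    if y_est.shape != y_act.shape:
        raise ValueError(f"length mismatch: {y_est.shape} vs {y_act.shape}")
    if y_est.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {y_est.size}")
    if not (np.isfinite(y_est).all() and np.isfinite(y_act).all()):
        raise ValueError("non-finite values in inputs")
    return y_est, y_act


def rmse(y_est, y_act) -> float:
    """Root mean square error, sqrt(mean((y_est - y_act)^2))."""
    y_est, y_act = _check_pair(y_est, y_act)
    return float(np.sqrt(np.mean((y_est - y_act) ** 2)))


def mae(y_est, y_act) -> float:
    """Mean absolute error."""
    y_est, y_act = _check_pair(y_est, y_act)
    return float(np.mean(np.abs(y_est - y_act)))


def r_squared(y_est, y_act) -> float:
    """Coefficient of determination, 1 - SSE/SST (SST about mean(y_act))."""
    y_est, y_act = _check_pair(y_est, y_act, min_n=2)
    sst = float(np.sum((y_act - y_act.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("y_act is constant; R^2 undefined")
    sse = float(np.sum((y_est - y_act) ** 2))
    return 1.0 - sse / sst


def overall_f_pvalue(y_est, y_act) -> float:
    """P-value of the overall F-test regressing observed on predicted.

    This is the "Pr > F" of the simple linear regression y_act ~ y_est
    (slope different from zero).  For models that are themselves linear
    regressions this coincides with the usual overall model F-test on one
    fitted degree of freedom; for non-regression surrogates it is the
    standard observed-vs-predicted significance convention.
    """
    y_est, y_act = _check_pair(y_est, y_act, min_n=3)
    if np.ptp(y_est) == 0.0:
        return 1.0  # constant predictor carries no information
    model = sm.OLS(y_act, sm.add_constant(y_est)).fit()
    return float(model.f_pvalue)


@dataclass(frozen=True)
class FitMetrics:
    """One model-comparison table cell group: R^2, RMSE, MAE (+ n, Pr>F)."""

    rmse: float
    mae: float
    r2: float
    n: int
    p_overall: float | None = None

    def __post_init__(self) -> None:
        if self.rmse < self.mae - 1e-12:
            raise ValueError("RMSE cannot be below MAE")
        if self.r2 > 1.0 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")


def evaluate(y_est, y_act, with_pvalue: bool = True) -> FitMetrics:
    """All criteria at once for one (prediction, observation) pair."""
    p = overall_f_pvalue(y_est, y_act) if with_pvalue and len(np.ravel(y_act)) >= 3 else None
    return FitMetrics(rmse=rmse(y_est, y_act), mae=mae(y_est, y_act),
                      r2=r_squared(y_est, y_act), n=int(np.ravel(y_act).size),
                      p_overall=p)
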