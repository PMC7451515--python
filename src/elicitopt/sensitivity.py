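"""Variable-exclusion sensitivity analysis (VSE / VSR).

The variable sensitivity error (VSE) of an input is the model RMSE when
that input is unavailable; the variable sensitivity ratio (VSR) divides it
by the RMSE of the full model, so VSR near 1 marks an uninformative input
and VSR well above 1 an influential one.  Inputs are ranked by descending
VSR.

"Unavailable" is implemented two ways: ``retrain_excluded`` retrains the
network on the remaining columns (the default — it measures what the model
loses without the variable, and redundant twins correctly show VSR near
1), and ``mean_substitute`` freezes the column at its training mean in the
full model (cheaper, but conflates a variable's importance with its
redundancy).  VSE is evaluated on the training subset by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anfis import AnfisConfig, predict, train_hybrid
from .data_model import DataSplit
from .metrics import rmse

MODES = ("retrain_excluded", "mean_substitute")


@dataclass(frozen=True)
class SensitivityReport:
    variable_names: tuple[str, ...]
    vse: tuple[float, ...]
    vsr: tuple[float, ...]
    baseline_rmse: float
    ranking: tuple[str, ...]

    def __post_init__(self) -> None:
        for e, r in zip(self.vse, self.vsr):
            if abs(r - e / self.baseline_rmse) > 1e-9 * max(1.0, r):
                raise ValueError("vsr must equal vse / baseline_rmse")
        if sorted(self.ranking) != sorted(self.variable_names):
            raise ValueError("ranking must be a permutation of variable names")


def _subset(split: DataSplit, evaluate_on: str):
    if evaluate_on == "train":
        return list(split.train_indices)
    if evaluate_on == "test":
        return list(split.test_indices)
    raise ValueError("evaluate_on must be 'train' or 'test'")


def vse(config: AnfisConfig, X, y, split: DataSplit, variable_index: int,
        mode: str = "retrain_excluded", evaluate_on: str = "train") -> float:
    """RMSE of the model with one input variable made unavailable."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    d = X.shape[1]
    if d < 2:
        raise ValueError("cannot exclude the only input variable")
    if not 0 <= variable_index < d:
        raise ValueError(f"variable_index must be in [0, {d})")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    tr = list(split.train_indices)
    ev = _subset(split, evaluate_on)
    if mode == "retrain_excluded":
        keep = [j for j in range(d) if j != variable_index]
        model = train_hybrid(config, X[np.ix_(tr, keep)], y[tr])
        return rmse(predict(X[np.ix_(ev, keep)], model), y[ev])
    model = train_hybrid(config, X[tr], y[tr])
    col_mean = X[tr, variable_index].mean()
    X_sub = X[ev].copy()
    X_sub[:, variable_index] = col_mean
    return rmse(predict(X_sub, model), y[ev])


def sensitivity_report(config: AnfisConfig, X, y, split: DataSplit,
                       mode: str = "retrain_excluded",
                       variable_names=None,
                       evaluate_on: str = "train") -> SensitivityReport:
    """Full VSE/VSR table with the descending-VSR importance ranking."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    d = X.shape[1]
    if variable_names is None:
        variable_names = tuple(f"x{j}" for j in range(d))
    variable_names = tuple(variable_names)
    if len(variable_names) != d:
        raise ValueError("one name per column required")
    tr = list(split.train_indices)
    ev = _subset(split, evaluate_on)
    full = train_hybrid(config, X[tr], y[tr])
    baseline = rmse(predict(X[ev], full), y[ev])
    vses = tuple(vse(config, X, y, split, j, mode, evaluate_on)
                 for j in range(d))
    vsrs = tuple(e / baseline for e in vses)
    order = np.argsort(vsrs)[::-1]
    return SensitivityReport(
        variable_names=variable_names,
        vse=vses,
        vsr=vsrs,
        baseline_rmse=baseline,
        ranking=tuple(variable_names[i] for i in order),
    )
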