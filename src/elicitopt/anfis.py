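"""Five-layer first-order Sugeno ANFIS with grid partition and hybrid learning.

The network implements the classic adaptive neuro-fuzzy inference system:

* layer 1 fuzzifies each input through parametric membership functions
  (generalized bell ``1 / (1 + |(x - c)/a|^(2b))`` by default, Gaussian as
  an option);
* layer 2 computes rule firing strengths as the product T-norm of the
  memberships selected by each rule of a full grid partition;
* layer 3 normalizes firing strengths to sum to one;
* layers 4-5 output the firing-strength-weighted sum of first-order
  (linear) rule consequents.

Training is hybrid: with premises fixed, the consequents are the exact
solution of a linear least-squares problem (with a small ridge guard); the
premise parameters {a, b, c} are then moved by one full-batch gradient
step on the squared-error loss, and the two passes alternate for a fixed
number of epochs.  Inputs are min-max scaled to [0, 1] and the response is
standardized internally; all public predictions are on original scales.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np

MF_FORMS = ("bell_eq3", "gaussian")

_A_MIN = 1e-6  # positivity clip for widths/shapes after gradient updates
_B_MIN = 1e-6


@dataclass(frozen=True)
class MembershipParams:
    """Premise parameter set {a, b, c}: width, shape exponent, center."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"width a and shape b must be positive, got a={self.a}, b={self.b}")


@dataclass(frozen=True)
class RuleBase:
    """Full Cartesian-product rule base over per-input membership functions."""

    mfs_per_input: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.mfs_per_input):
            raise ValueError("every input needs at least one membership function")

    @property
    def rules(self) -> np.ndarray:
        """(n_rules, d) array; row k gives rule k's MF index for each input."""
        return np.array(list(itertools.product(
            *(range(m) for m in self.mfs_per_input))), dtype=int)

    @property
    def n_rules(self) -> int:
        return int(np.prod(self.mfs_per_input))


@dataclass(frozen=True)
class AnfisConfig:
    """Architecture and training hyperparameters.

    ``mfs_per_input`` may be a single count applied to every input or a
    per-input tuple.  ``learning_rate`` scales the per-observation average
    premise gradient, so the step size does not grow with sample size.
    ``ridge`` stabilizes the consequent least-squares solve against weakly
    firing rules (set 0 to disable).
    """

    mfs_per_input: int | tuple[int, ...] = 2
    mf_form: str = "bell_eq3"
    epochs: int = 100
    learning_rate: float = 0.01
    normalize_inputs: bool = True
    seed: int = 0
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if self.mf_form not in MF_FORMS:
            raise ValueError(f"mf_form must be one of {MF_FORMS}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")
        counts = ((self.mfs_per_input,) if isinstance(self.mfs_per_input, int)
                  else tuple(self.mfs_per_input))
        if any(m < 2 for m in counts):
            raise ValueError("need at least 2 membership functions per input")

    def mf_counts(self, d: int) -> tuple[int, ...]:
        if isinstance(self.mfs_per_input, int):
            return (self.mfs_per_input,) * d
        return tuple(self.mfs_per_input)


@dataclass
class AnfisModel:
    """A parameterized ANFIS: scaling, premises, rule base, consequents.

    ``premise[j]`` is an (m_j, 3) array of rows (a, b, c) on the internal
    normalized input scale.  ``consequents`` is (n_rules, d + 1) — the
    linear coefficients and intercept of each rule on the normalized input
    / standardized output scale.  ``y_offset``/``y_scale`` map internal
    outputs back to response units.
    """

    config: AnfisConfig
    input_ranges: tuple[tuple[float, float], ...]
    premise: list[np.ndarray]
    rulebase: RuleBase
    consequents: np.ndarray | None = None
    training_history: list[float] = field(default_factory=list)
    y_offset: float = 0.0
    y_scale: float = 1.0

    @property
    def d(self) -> int:
        return len(self.input_ranges)

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        if not self.config.normalize_inputs:
            return X
        lo = np.array([r[0] for r in self.input_ranges])
        hi = np.array([r[1] for r in self.input_ranges])
        width = np.where(hi > lo, hi - lo, 1.0)
        return (X - lo) / width

    def membership_params(self, input_index: int, mf_index: int) -> MembershipParams:
        a, b, c = self.premise[input_index][mf_index]
        return MembershipParams(a=float(a), b=float(b), c=float(c))


def mf_value(x, params: MembershipParams, form: str = "bell_eq3"):
    """Membership degree of ``x`` in the fuzzy set defined by ``params``.

    ``bell_eq3`` is the generalized bell 1 / (1 + |(x - c)/a|^(2b));
    ``gaussian`` is exp(-(x - c)^2 / (2 a^2)).  Both peak at 1 when x = c,
    and the bell form is strictly positive everywhere.
    """
    if form not in MF_FORMS:
        raise ValueError(f"unknown membership form {form!r}")
    if params.a <= 0 or params.b <= 0:
        raise ValueError("membership parameters a and b must be positive")
    x = np.asarray(x, dtype=float)
    if form == "bell_eq3":
        val = 1.0 / (1.0 + np.abs((x - params.c) / params.a) ** (2.0 * params.b))
    else:
        val = np.exp(-((x - params.c) ** 2) / (2.0 * params.a ** 2))
    return float(val) if np.ndim(val) == 0 else val


def _membership_matrix(model: AnfisModel, Xn: np.ndarray) -> list[np.ndarray]:
    """Per-input membership degrees on normalized inputs: list of (n, m_j)."""
    out = []
    for j in range(model.d):
        a = model.premise[j][:, 0]
        b = model.premise[j][:, 1]
        c = model.premise[j][:, 2]
        x = Xn[:, j][:, None]
        if model.config.mf_form == "bell_eq3":
            mu = 1.0 / (1.0 + np.abs((x - c) / a) ** (2.0 * b))
        else:
            mu = np.exp(-((x - c) ** 2) / (2.0 * a ** 2))
        out.append(mu)
    return out


def _firing_matrix(model: AnfisModel, Xn: np.ndarray) -> np.ndarray:
    """(n, n_rules) firing strengths via product T-norm."""
    mus = _membership_matrix(model, Xn)
    rules = model.rulebase.rules
    w = np.ones((Xn.shape[0], rules.shape[0]))
    for j in range(model.d):
        w *= mus[j][:, rules[:, j]]
    return w


def firing_strengths(x, model: AnfisModel) -> np.ndarray:
    """Rule firing strengths for one input vector (original units)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.d,):
        raise ValueError(f"expected input of length {model.d}, got shape {x.shape}")
    Xn = model._normalize(x[None, :])
    return _firing_matrix(model, Xn)[0]


def normalize_firing(w) -> np.ndarray:
    """Normalize firing strengths to sum to one."""
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("firing strengths must be non-negative")
    s = w.sum()
    if s <= 0:
        raise ValueError("all firing strengths are zero")
    return w / s


def _regressor_matrix(model: AnfisModel, Xn: np.ndarray) -> np.ndarray:
    """LSE design: row i has blocks wbar_k(x_i) * (x_i, 1) for each rule."""
    w = _firing_matrix(model, Xn)
    wbar = w / w.sum(axis=1, keepdims=True)
    Xaug = np.hstack([Xn, np.ones((Xn.shape[0], 1))])
    n, K = wbar.shape
    return (wbar[:, :, None] * Xaug[:, None, :]).reshape(n, K * (model.d + 1))


def _forward_internal(model: AnfisModel, Xn: np.ndarray) -> np.ndarray:
    theta = model.consequents.reshape(-1)
    return _regressor_matrix(model, Xn) @ theta


def predict(x, model: AnfisModel):
    """Model output for a length-d vector or (n, d) matrix, response units."""
    if model.consequents is None:
        raise ValueError("model has no consequent parameters; train it first")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != model.d:
        raise ValueError(f"expected {model.d} inputs, got {X.shape[1]}")
    yhat = model.y_offset + model.y_scale * _forward_internal(model, model._normalize(X))
    return float(yhat[0]) if single else yhat


def initialize_model(config: AnfisConfig,
                     input_ranges) -> AnfisModel:
    """Grid-partition initialization over the input ranges.

    Membership centers are evenly spaced across each (normalized) input
    range, widths are half the center spacing, and the bell shape exponent
    starts at 2 — the standard overlapping coverage that keeps every rule
    strictly positive everywhere.
    """
    input_ranges = tuple((float(lo), float(hi)) for lo, hi in input_ranges)
    d = len(input_ranges)
    counts = config.mf_counts(d)
    if len(counts) != d:
        raise ValueError(f"mfs_per_input has {len(counts)} entries for {d} inputs")
    premise = []
    for j, m in enumerate(counts):
        if config.normalize_inputs:
            lo, hi = 0.0, 1.0
        else:
            lo, hi = input_ranges[j]
            if hi <= lo:
                lo, hi = lo, lo + 1.0
        centers = np.linspace(lo, hi, m)
        spacing = (hi - lo) / (m - 1)
        a = np.full(m, spacing / 2.0)
        b = np.full(m, 2.0)
        premise.append(np.column_stack([a, b, centers]).astype(float))
    return AnfisModel(config=config, input_ranges=input_ranges,
                      premise=premise, rulebase=RuleBase(tuple(counts)))


def lse_consequents(model: AnfisModel, X, y) -> np.ndarray:
    """Least-squares estimate of all rule consequents, premises fixed.

    Solves the global linear problem in the stacked coefficient vector with
    ridge regularization ``config.ridge`` (exact least squares when 0).
    The model is updated in place and the (n_rules, d+1) coefficient array
    returned.  ``y`` is taken on the model's internal response scale
    mapping, i.e. raw response units.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xn = model._normalize(X)
    yn = (y - model.y_offset) / model.y_scale
    Phi = _regressor_matrix(model, Xn)
    p = Phi.shape[1]
    if model.config.ridge > 0:
        A = Phi.T @ Phi + model.config.ridge * np.eye(p)
        theta = np.linalg.solve(A, Phi.T @ yn)
    else:
        theta, _, rank, _ = np.linalg.lstsq(Phi, yn, rcond=None)
        if rank < p:
            raise np.linalg.LinAlgError(
                f"rank-deficient consequent system (rank {rank} < {p}); "
                "set ridge > 0 to regularize")
    model.consequents = theta.reshape(model.rulebase.n_rules, model.d + 1)
    return model.consequents


def premise_gradient(model: AnfisModel, X, y) -> list[np.ndarray]:
    """Analytic gradient of the SSE w.r.t. every premise parameter.

    Returns one (m_j, 3) array per input with columns (dSSE/da, dSSE/db,
    dSSE/dc), computed on the internal scales (matching finite differences
    of the internal SSE).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xn = model._normalize(X)
    yn = (y - model.y_offset) / model.y_scale
    mus = _membership_matrix(model, Xn)
    rules = model.rulebase.rules
    n, d = Xn.shape
    K = rules.shape[0]

    w = np.ones((n, K))
    for j in range(d):
        w *= mus[j][:, rules[:, j]]
    S = w.sum(axis=1, keepdims=True)
    wbar = w / S
    Xaug = np.hstack([Xn, np.ones((n, 1))])
    F = Xaug @ model.consequents.T          # (n, K): rule outputs
    yhat = (wbar * F).sum(axis=1)
    e = yhat - yn
    # dSSE/dw_k = 2 e (F_k - yhat) / S ; chain through w_k = prod_j mu
    G = (2.0 * e[:, None]) * (F - yhat[:, None]) / S * w   # (n, K)

    grads = []
    for j in range(d):
        m = model.premise[j].shape[0]
        a = model.premise[j][:, 0]
        b = model.premise[j][:, 1]
        c = model.premise[j][:, 2]
        # sum G over rules using MF m of input j, divided by that mu
        Gj = np.zeros((n, m))
        for mf in range(m):
            mask = rules[:, j] == mf
            Gj[:, mf] = G[:, mask].sum(axis=1)
        mu = mus[j]
        dmu = Gj / np.maximum(mu, 1e-300)    # dSSE/dmu, (n, m)
        x = Xn[:, j][:, None]
        if model.config.mf_form == "bell_eq3":
            u = ((x - c) / a) ** 2
            dmu_du = -b * np.where(u > 0, u ** (b - 1.0), 0.0) * mu ** 2
            du_da = -2.0 * (x - c) ** 2 / a ** 3
            du_dc = -2.0 * (x - c) / a ** 2
            with np.errstate(divide="ignore", invalid="ignore"):
                dmu_db = np.where(u > 0, -(mu ** 2) * u ** b * np.log(np.maximum(u, 1e-300)), 0.0)
            ga = (dmu * dmu_du * du_da).sum(axis=0)
            gb = (dmu * dmu_db).sum(axis=0)
            gc = (dmu * dmu_du * du_dc).sum(axis=0)
        else:  # gaussian; b is inert
            ga = (dmu * mu * (x - c) ** 2 / a ** 3).sum(axis=0)
            gb = np.zeros(m)
            gc = (dmu * mu * (x - c) / a ** 2).sum(axis=0)
        g = np.column_stack([ga, gb, gc])
        if not np.isfinite(g).all():
            raise FloatingPointError("non-finite premise gradient")
        grads.append(g)
    return grads


def backprop_premise(model: AnfisModel, X, y,
                     learning_rate: float | None = None) -> list[np.ndarray]:
    """One full-batch gradient-descent step on all premise parameters.

    The step is ``learning_rate`` times the per-observation average
    gradient (dSSE / n), keeping step sizes comparable across sample
    sizes.  Widths and shape exponents are clipped to stay positive.
    Updates the model in place and returns the new premise arrays.
    """
    lr = model.config.learning_rate if learning_rate is None else learning_rate
    if lr == 0.0:
        return model.premise
    n = np.asarray(X).shape[0]
    grads = premise_gradient(model, X, y)
    for j, g in enumerate(grads):
        p = model.premise[j] - lr * g / n
        p[:, 0] = np.maximum(p[:, 0], _A_MIN)
        p[:, 1] = np.maximum(p[:, 1], _B_MIN)
        model.premise[j] = p
    return model.premise


def train_hybrid(config: AnfisConfig, X, y) -> AnfisModel:
    """Fit an ANFIS by alternating consequent LSE and premise gradient steps.

    Each epoch solves the consequents exactly, records the training RMSE,
    then takes one premise gradient step.  The returned model carries the
    best (premises, consequents) snapshot seen, so its final training RMSE
    never exceeds the initial one; ``training_history`` has one RMSE per
    epoch.  Fully deterministic for a given config and data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, d) with y of length n")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite training data")

    ranges = tuple((float(X[:, j].min()), float(X[:, j].max()))
                   for j in range(X.shape[1]))
    model = initialize_model(config, ranges)
    model.y_offset = float(y.mean())
    spread = float(y.std())
    model.y_scale = spread if spread > 0 else 1.0

    from .metrics import rmse as _rmse

    best = None
    history = []
    for epoch in range(config.epochs):
        lse_consequents(model, X, y)
        err = _rmse(predict(X, model), y)
        if not np.isfinite(err) or err > 1e12 * (model.y_scale + 1.0):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} (RMSE={err:.3g}); "
                "try a smaller learning_rate")
        history.append(err)
        if best is None or err < best[0]:
            best = (err, [p.copy() for p in model.premise],
                    model.consequents.copy())
        if epoch < config.epochs - 1:
            backprop_premise(model, X, y)
    # final model = best snapshot; history keeps the full trajectory
    _, model.premise, model.consequents = best
    model.training_history = history
    return model


def to_json(model: AnfisModel) -> str:
    """Serialize a fitted model to a versioned JSON document."""
    doc = {
        "format": "elicitopt-anfis",
        "version": 1,
        "config": {
            "mfs_per_input": (model.config.mfs_per_input
                              if isinstance(model.config.mfs_per_input, int)
                              else list(model.config.mfs_per_input)),
            "mf_form": model.config.mf_form,
            "epochs": model.config.epochs,
            "learning_rate": model.config.learning_rate,
            "normalize_inputs": model.config.normalize_inputs,
            "seed": model.config.seed,
            "ridge": model.config.ridge,
        },
        "input_ranges": [list(r) for r in model.input_ranges],
        "premise": [p.tolist() for p in model.premise],
        "mfs_per_input": list(model.rulebase.mfs_per_input),
        "consequents": None if model.consequents is None else model.consequents.tolist(),
        "training_history": list(model.training_history),
        "y_offset": model.y_offset,
        "y_scale": model.y_scale,
    }
    return json.dumps(doc, indent=2)


def from_json(text: str) -> AnfisModel:
    """Reload a model serialized by :func:`to_json`."""
    doc = json.loads(text)
    if doc.get("format") != "elicitopt-anfis":
        raise ValueError("not an elicitopt ANFIS document")
    cfg = doc["config"]
    if isinstance(cfg["mfs_per_input"], list):
        cfg["mfs_per_input"] = tuple(cfg["mfs_per_input"])
    config = AnfisConfig(**cfg)
    model = AnfisModel(
        config=config,
        input_ranges=tuple((float(lo), float(hi)) for lo, hi in doc["input_ranges"]),
        premise=[np.asarray(p, dtype=float) for p in doc["premise"]],
        rulebase=RuleBase(tuple(doc["mfs_per_input"])),
        consequents=(None if doc["consequents"] is None
                     else np.asarray(doc["consequents"], dtype=float)),
        training_history=list(doc["training_history"]),
        y_offset=float(doc["y_offset"]),
        y_scale=float(doc["y_scale"]),
    )
    return model
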