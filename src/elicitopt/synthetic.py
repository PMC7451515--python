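"""Synthetic factorial elicitation datasets with a known ground truth.

The original measurements behind this kind of study are rarely deposited,
so the package ships a generator that reproduces the *design* of the
experiment — a randomized complete block design crossing elicitor
concentration, MBCD level, elicitor adding day and a harvest schedule —
and overlays a known nonlinear response surface plus Gaussian block and
residual noise.  Because the surface is known in closed form, model fit,
sensitivity rankings and optimizer recovery can all be checked against
exact oracles.

The surface multiplies two bell-shaped kernels (dose and elapsed time
after elicitation) with linear synergy (MBCD) and timing (adding day)
multipliers:

    y = beta0 + A * B(conc; c*, a_c, b_c) * B(dt; tau*, a_t, b_t)
             * (1 + s * mbcd / 50) * (1 + delta * (adding_day - 13) / 4)

where B(x; c, a, b) = 1 / (1 + |(x - c)/a|^(2b)) is the generalized bell
kernel (the same functional form the fuzzy memberships use) and
dt = harvest_day - adding_day is the elapsed time.  With the defaults the
true optimum sits at an interior dose (3 % v/v), interior elapsed time
(6 days), maximal MBCD (50 mM) and the late adding day (17).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .data_model import ElicitationRecord, ExperimentTable


@dataclass(frozen=True)
class DesignSpec:
    """Factor levels and harvest schedule of the factorial design.

    Defaults follow the elicitation protocol the generator emulates: doses
    0 (control), 1, 2.5, 5, 10 % v/v; MBCD absent or 50 mM; elicitation at
    mid (day 13) or late (day 17) log phase; harvests every 2 days after
    elicitation until culture day 23; three replicate blocks.
    """

    elicitor_concs: tuple[float, ...] = (0.0, 1.0, 2.5, 5.0, 10.0)
    mbcd_levels: tuple[float, ...] = (0.0, 50.0)
    adding_days: tuple[float, ...] = (13.0, 17.0)
    harvest_step: float = 2.0
    last_harvest_day: float = 23.0
    n_blocks: int = 3

    def __post_init__(self) -> None:
        if not (self.elicitor_concs and self.mbcd_levels and self.adding_days):
            raise ValueError("factor level lists must be non-empty")
        if self.harvest_step <= 0:
            raise ValueError("harvest_step must be positive")
        if self.last_harvest_day <= max(self.adding_days):
            raise ValueError("last_harvest_day must exceed every adding day")
        if self.n_blocks < 1:
            raise ValueError("need at least one block")

    def harvest_days(self, adding_day: float) -> tuple[float, ...]:
        """Harvest schedule for one adding day: d+step, d+2*step, ... <= last."""
        days = []
        t = adding_day + self.harvest_step
        while t <= self.last_harvest_day + 1e-9:
            days.append(t)
            t += self.harvest_step
        return tuple(days)

    @property
    def n_rows(self) -> int:
        """Row count of the full crossing (one elicitor type)."""
        n_harvests = sum(len(self.harvest_days(d)) for d in self.adding_days)
        return (len(self.elicitor_concs) * len(self.mbcd_levels)
                * n_harvests * self.n_blocks)


@dataclass(frozen=True)
class SyntheticSurfaceSpec:
    """Parameters of the ground-truth response surface (units in docstring).

    beta0, A, sigma_block and sigma_eps are in micrograms per litre; c_star
    and a_c in % v/v; tau_star and a_t in days; b_c, b_t, s and delta are
    dimensionless.
    """

    beta0: float = 30.0
    A: float = 300.0
    c_star: float = 3.0
    a_c: float = 2.5
    b_c: float = 1.5
    tau_star: float = 6.0
    a_t: float = 3.0
    b_t: float = 2.0
    s: float = 0.6
    delta: float = 0.15
    sigma_block: float = 5.0
    sigma_eps: float = 15.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("amplitude A must be positive")
        if min(self.a_c, self.b_c, self.a_t, self.b_t) <= 0:
            raise ValueError("bell widths and shapes must be positive")
        if self.sigma_block < 0 or self.sigma_eps < 0:
            raise ValueError("noise SDs must be non-negative")


def _bell(x, center: float, a: float, b: float):
    return 1.0 / (1.0 + np.abs((np.asarray(x, dtype=float) - center) / a) ** (2.0 * b))


def true_response(x, spec: SyntheticSurfaceSpec = SyntheticSurfaceSpec()):
    """Noiseless ground-truth response at input(s) (conc, mbcd, adding, harvest).

    Accepts a length-4 vector or an (n, 4) array; returns a scalar or
    length-n array of micrograms per litre.  Raises if any harvest day is
    not after its adding day.
    """
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    conc, mbcd, adding, harvest = arr.T
    dt = harvest - adding
    if np.any(dt <= 0):
        raise ValueError("harvest_day must be after adding_day")
    y = spec.beta0 + (
        spec.A
        * _bell(conc, spec.c_star, spec.a_c, spec.b_c)
        * _bell(dt, spec.tau_star, spec.a_t, spec.b_t)
        * (1.0 + spec.s * mbcd / 50.0)
        * (1.0 + spec.delta * (adding - 13.0) / 4.0)
    )
    return float(y[0]) if np.ndim(x) == 1 else y


def generate_design(spec: DesignSpec = DesignSpec(),
                    elicitor: str = "CE") -> ExperimentTable:
    """Full factorial crossing with responses unset (recorded as 0).

    Rows are ordered block-major, then concentration, MBCD, adding day,
    harvest day — a stable order so that seeded noise is reproducible.
    """
    records = []
    for block in range(1, spec.n_blocks + 1):
        for conc, mbcd, adding in itertools.product(
                spec.elicitor_concs, spec.mbcd_levels, spec.adding_days):
            for harvest in spec.harvest_days(adding):
                records.append(ElicitationRecord(
                    elicitor_type=elicitor,
                    elicitor_conc=conc,
                    mbcd_conc=mbcd,
                    adding_day=adding,
                    harvest_day=harvest,
                    block_id=f"B{block}",
                    paclitaxel=0.0,
                ))
    if not records:
        raise ValueError("design crossing is empty")
    return ExperimentTable(records=records,
                           metadata={"design": "rcbd_factorial",
                                     "elicitor": elicitor})


def generate_dataset(design: DesignSpec = DesignSpec(),
                     surface: SyntheticSurfaceSpec = SyntheticSurfaceSpec(),
                     seed: int = 0, elicitor: str = "CE") -> ExperimentTable:
    """Design crossing plus ground-truth response, block effects and noise.

    Observed response is ``max(0, truth + block_effect + eps)`` with the
    block effect Normal(0, sigma_block^2) shared by all rows of a block and
    eps i.i.d. Normal(0, sigma_eps^2).  Same seed, same table.
    """
    table = generate_design(design, elicitor)
    rng = np.random.default_rng(seed)
    block_effects = {f"B{b}": rng.normal(0.0, surface.sigma_block)
                     for b in range(1, design.n_blocks + 1)}
    records = []
    for rec in table.records:
        mu = true_response(np.array([rec.elicitor_conc, rec.mbcd_conc,
                                     rec.adding_day, rec.harvest_day]),
                           surface)
        y = mu + block_effects[rec.block_id] + rng.normal(0.0, surface.sigma_eps)
        records.append(ElicitationRecord(
            elicitor_type=rec.elicitor_type,
            elicitor_conc=rec.elicitor_conc,
            mbcd_conc=rec.mbcd_conc,
            adding_day=rec.adding_day,
            harvest_day=rec.harvest_day,
            block_id=rec.block_id,
            paclitaxel=max(0.0, float(y)),
        ))
    meta = {"seed": seed, "elicitor": elicitor, "design": "rcbd_factorial",
            "surface": {k: getattr(surface, k)
                        for k in SyntheticSurfaceSpec.__dataclass_fields__}}
    return ExperimentTable(records=records, metadata=meta)


@dataclass(frozen=True)
class GridBounds:
    """Box bounds over (conc, mbcd, adding_day, elapsed_days)."""

    conc: tuple[float, float] = (0.0, 10.0)
    mbcd: tuple[float, float] = (0.0, 50.0)
    adding_day: tuple[float, float] = (13.0, 17.0)
    elapsed: tuple[float, float] = (2.0, 10.0)

    def as_tuples(self):
        return (self.conc, self.mbcd, self.adding_day, self.elapsed)


def true_optimum(bounds: GridBounds = GridBounds(),
                 surface: SyntheticSurfaceSpec = SyntheticSurfaceSpec(),
                 grid_step: tuple[float, float, float, float] = (0.05, 1.0, 0.25, 0.05),
                 ) -> tuple[np.ndarray, float]:
    """Brute-force grid maximum of the true surface.

    Searches (conc, mbcd, adding_day, elapsed) on a regular grid inside the
    box and returns the best point as (conc, mbcd, adding_day, harvest_day)
    plus the maximal noiseless response.  Serves as the oracle that the
    model-based optimizer is compared against.  Evaluation is chunked over
    the dose axis to keep memory flat on fine grids.
    """
    axes = []
    for (lo, hi), step in zip(bounds.as_tuples(), grid_step):
        if step <= 0:
            raise ValueError("grid steps must be positive")
        if hi <= lo:
            raise ValueError(f"degenerate bounds ({lo}, {hi})")
        axes.append(np.arange(lo, hi + step / 2, step))
    best_pt, best_val = None, -np.inf
    mbcd, adding, dt = np.meshgrid(axes[1], axes[2], axes[3], indexing="ij")
    base = np.column_stack([np.zeros(mbcd.size), mbcd.ravel(), adding.ravel(),
                            (adding + dt).ravel()])
    for conc in axes[0]:
        base[:, 0] = conc
        vals = true_response(base, surface)
        k = int(np.argmax(vals))
        if vals[k] > best_val:
            best_val = float(vals[k])
            best_pt = base[k].copy()
    return best_pt, best_val


def oracle_partial_effect_ranges(bounds: GridBounds = GridBounds(),
                                 surface: SyntheticSurfaceSpec = SyntheticSurfaceSpec(),
                                 n_grid: int = 9) -> dict[str, float]:
    """True main-effect range of each input, averaged over the others.

    For each variable, the range (max - min) of the true response as that
    variable sweeps its bounds is computed at every grid combination of the
    remaining variables, then averaged.  The resulting ordering is the
    ground-truth importance ranking that sensitivity analysis should
    recover.
    """
    names = ("elicitor_conc", "mbcd_conc", "adding_day", "harvest_day")
    grids = [np.linspace(lo, hi, n_grid) for lo, hi in bounds.as_tuples()]
    out = {}
    for j, name in enumerate(names):
        others = [grids[i] for i in range(4) if i != j]
        ranges = []
        for combo in itertools.product(*others):
            pts = []
            for v in grids[j]:
                vec = list(combo)
                vec.insert(j, v)
                conc, mbcd, adding, dt = vec
                pts.append([conc, mbcd, adding, adding + dt])
            vals = true_response(np.array(pts), surface)
            ranges.append(vals.max() - vals.min())
        out[name] = float(np.mean(ranges))
    return out
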