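"""End-to-end orchestration: data, per-elicitor models, comparison tables,
sensitivity and model-based optimization.

A run mirrors the shape of an elicitation-optimization study: for each
elicitor type, the observations are split 75/25 into training and testing
subsets, the fuzzy-neural surrogate and five linear baselines are fitted
on the training subset and evaluated on both, the variable-exclusion
sensitivity analysis ranks the inputs, and a genetic algorithm maximizes
the fitted surrogate over the elicitation conditions.  Reports come out as
a model-comparison table (per-model R^2/RMSE/MAE and overall significance
for both subsets), a sensitivity + optimal-levels table, and a
predicted-versus-observed listing for the held-out subset.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anfis import AnfisConfig, predict, to_json, train_hybrid
from .baselines import fit_all
from .data_model import (DataSplit, ExperimentTable, INPUT_COLUMNS,
                         read_experiment_csv, split_train_test,
                         to_design_matrix)
from .ga import DEFAULT_BOUNDS, GAConfig, VariableBounds, optimize_model
from .metrics import evaluate
from .sensitivity import sensitivity_report
from .synthetic import DesignSpec, SyntheticSurfaceSpec, generate_dataset

log = logging.getLogger("elicitopt")

MODEL_ORDER = ("MLR", "SR", "PLSR", "PCR", "OLSR", "ANFIS")


@dataclass(frozen=True)
class ElapsedTime:
    """Time after elicitation expressed as hours + minutes.

    Minutes are rounded to the nearest minute from the decimal-hour value,
    which is how optimal harvest times are conventionally reported.
    """

    hours: int
    minutes: int
    decimal_hours: float

    def __post_init__(self) -> None:
        if self.hours < 0 or not 0 <= self.minutes <= 59:
            raise ValueError("hours must be >= 0 and minutes in [0, 59]")
        if abs(self.decimal_hours - (self.hours + self.minutes / 60.0)) > 1.0 / 120.0 + 1e-9:
            raise ValueError("hours/minutes inconsistent with decimal_hours")

    def __str__(self) -> str:
        if self.minutes == 0:
            return f"{self.hours} h"
        return f"{self.hours} h and {self.minutes} min"


def elapsed_after_elicitation(adding_day: float, harvest_day: float) -> ElapsedTime:
    """Convert culture days to elapsed time after elicitation.

    ``decimal_hours = (harvest_day - adding_day) * 24``; the h/min display
    rounds the total to the nearest minute (e.g. 98.88 h -> 98 h 53 min).
    """
    if harvest_day <= adding_day:
        raise ValueError("harvest_day must be after adding_day")
    decimal_hours = (harvest_day - adding_day) * 24.0
    total_minutes = int(round(decimal_hours * 60.0))
    return ElapsedTime(hours=total_minutes // 60, minutes=total_minutes % 60,
                       decimal_hours=decimal_hours)


@dataclass
class PipelineConfig:
    """Everything a run needs; either a CSV path or synthetic specs."""

    csv_path: str | None = None
    design: DesignSpec = field(default_factory=DesignSpec)
    surface: SyntheticSurfaceSpec = field(default_factory=SyntheticSurfaceSpec)
    data_seed: int = 0
    elicitors: tuple[str, ...] = ("CE",)
    split_fraction: float = 0.75
    split_seed: int = 0
    anfis: AnfisConfig = field(default_factory=AnfisConfig)
    stepwise_alphas: tuple[float, float] = (0.05, 0.10)
    pcr_components: int | None = None
    plsr_components: int | None = None
    ga: GAConfig = field(default_factory=GAConfig)
    bounds: VariableBounds = DEFAULT_BOUNDS
    sensitivity_mode: str = "retrain_excluded"
    outdir: str = "results"

    def digest(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


@dataclass
class PipelineReport:
    """All tables of one run plus provenance, JSON-serializable."""

    metrics: pd.DataFrame               # model comparison, long format
    sensitivity: pd.DataFrame           # per-elicitor VSE/VSR table
    optima: pd.DataFrame                # per-elicitor optimal levels/output
    predicted_observed: pd.DataFrame    # held-out pairs per model
    provenance: dict
    models_json: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics.to_dict(orient="records"),
            "sensitivity": self.sensitivity.to_dict(orient="records"),
            "optima": self.optima.to_dict(orient="records"),
            "predicted_observed": self.predicted_observed.to_dict(orient="records"),
            "provenance": self.provenance,
            "models": self.models_json,
        }


def _load_table(config: PipelineConfig, elicitor: str) -> ExperimentTable:
    if config.csv_path is not None:
        return read_experiment_csv(config.csv_path)
    return generate_dataset(config.design, config.surface,
                            seed=config.data_seed, elicitor=elicitor)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Fit, evaluate, rank and optimize for every selected elicitor."""
    metric_rows, sens_rows, opt_rows, pairs_rows = [], [], [], []
    models_json: dict = {}
    for elicitor in config.elicitors:
        log.info("elicitor %s: loading data", elicitor)
        table = _load_table(config, elicitor)
        dm = to_design_matrix(table, elicitor)
        split = split_train_test_matrix(dm.n, config.split_fraction,
                                        config.split_seed)
        tr, te = list(split.train_indices), list(split.test_indices)
        X, y = dm.X, dm.y
        log.info("elicitor %s: n=%d (train %d / test %d)", elicitor,
                 dm.n, len(tr), len(te))

        fits = {}
        for name, lm in fit_all(X[tr], y[tr],
                                stepwise_alphas=config.stepwise_alphas,
                                pcr_k=config.pcr_components,
                                plsr_k=config.plsr_components).items():
            fits[name] = lm.predict
        anfis_model = train_hybrid(config.anfis, X[tr], y[tr])
        fits["ANFIS"] = lambda Z, m=anfis_model: predict(np.atleast_2d(Z), m)
        models_json[elicitor] = {"anfis": json.loads(to_json(anfis_model))}

        for name in MODEL_ORDER:
            pred = fits[name]
            for subset, idx in (("train", tr), ("test", te)):
                fm = evaluate(pred(X[idx]), y[idx])
                metric_rows.append({
                    "elicitor": elicitor, "model": name, "subset": subset,
                    "r2": fm.r2, "rmse": fm.rmse, "mae": fm.mae,
                    "n": fm.n, "p_overall": fm.p_overall,
                })
            yhat = pred(X[te])
            for i, row in enumerate(te):
                pairs_rows.append({
                    "elicitor": elicitor, "model": name, "row": row,
                    "observed": float(y[row]), "predicted": float(yhat[i]),
                })

        log.info("elicitor %s: sensitivity analysis (%s)", elicitor,
                 config.sensitivity_mode)
        sens = sensitivity_report(config.anfis, X, y, split,
                                  mode=config.sensitivity_mode,
                                  variable_names=INPUT_COLUMNS)
        for name, e, r in zip(sens.variable_names, sens.vse, sens.vsr):
            sens_rows.append({"elicitor": elicitor, "variable": name,
                              "vse": e, "vsr": r,
                              "baseline_rmse": sens.baseline_rmse,
                              "rank": sens.ranking.index(name) + 1})

        log.info("elicitor %s: GA optimization", elicitor)
        # cap candidate harvests at the last day the data cover: the
        # surrogate has no support beyond the harvest schedule
        res = optimize_model(fits["ANFIS"], config.bounds, config.ga,
                             max_harvest_day=float(X[:, 3].max()))
        conc, mbcd, adding, elapsed = res.best_inputs
        harvest = adding + elapsed
        et = elapsed_after_elicitation(adding, harvest)
        opt_rows.append({
            "elicitor": elicitor,
            "elicitor_conc": float(conc), "mbcd_conc": float(mbcd),
            "adding_day": float(adding), "harvest_day": float(harvest),
            "elapsed_hours": et.decimal_hours,
            "elapsed_hmin": str(et),
            "predicted_max": float(res.best_predicted),
        })

    provenance = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "data_seed": config.data_seed,
        "split_seed": config.split_seed,
        "anfis_seed": config.anfis.seed,
        "ga_seed": config.ga.seed,
        "source": config.csv_path or "synthetic",
    }
    return PipelineReport(
        metrics=pd.DataFrame(metric_rows),
        sensitivity=pd.DataFrame(sens_rows),
        optima=pd.DataFrame(opt_rows),
        predicted_observed=pd.DataFrame(pairs_rows),
        provenance=provenance,
        models_json=models_json,
    )


def split_train_test_matrix(n: int, fraction: float, seed: int) -> DataSplit:
    """Split helper for an already-extracted design matrix of n rows."""
    if n < 2:
        raise ValueError("need at least 2 rows")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_train = int(np.round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return DataSplit(train_indices=tuple(int(i) for i in np.sort(perm[:n_train])),
                     test_indices=tuple(int(i) for i in np.sort(perm[n_train:])),
                     seed=seed, fraction=fraction)


def write_report(report: PipelineReport, outdir) -> list[Path]:
    """Write the four report artifacts; returns the created paths.

    ``metrics.csv`` is the model-comparison table, ``sensitivity_optima.csv``
    merges the importance and optimal-level columns,
    ``predicted_observed.csv`` holds the held-out pairs, and
    ``report.json`` carries everything (full precision) plus provenance.
    A plain-text log records the headline numbers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    p = outdir / "metrics.csv"
    report.metrics.round(2).to_csv(p, index=False)
    paths.append(p)

    merged = report.sensitivity.merge(report.optima, on="elicitor")
    p = outdir / "sensitivity_optima.csv"
    merged.round(2).to_csv(p, index=False)
    paths.append(p)

    p = outdir / "predicted_observed.csv"
    report.predicted_observed.round(2).to_csv(p, index=False)
    paths.append(p)

    p = outdir / "report.json"
    p.write_text(json.dumps(report.to_dict(), indent=2, default=float))
    paths.append(p)

    lines = [f"elicitopt {report.provenance['package_version']} "
             f"config {report.provenance['config_digest']}"]
    for _, row in report.optima.iterrows():
        lines.append(
            f"{row['elicitor']}: optimum conc={row['elicitor_conc']:.2f} %v/v, "
            f"MBCD={row['mbcd_conc']:.2f} mM, adding day {row['adding_day']:.2f}, "
            f"harvest day {row['harvest_day']:.2f} ({row['elapsed_hmin']} "
            f"after elicitation), predicted {row['predicted_max']:.2f} ug/l")
    p = outdir / "run.log"
    p.write_text("\n".join(lines) + "\n")
    paths.append(p)
    return paths
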