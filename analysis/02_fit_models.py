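#!/usr/bin/env python
"""Fit the fuzzy-neural surrogate and the five linear baselines.

For each elicitor dataset written by 01_simulate.py: split 75/25, train
ANFIS and MLR/SR/PLSR/PCR/OLSR on the training subset, and tabulate
R^2/RMSE/MAE and the overall F-test p-value for both subsets
(model-comparison table).  The expected finding is the large gap between
the fuzzy network (test R^2 around 0.9 on the curved surface) and every
main-effects linear model.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from elicitopt.anfis import AnfisConfig, predict, train_hybrid
from elicitopt.baselines import fit_all
from elicitopt.data_model import read_experiment_csv, to_design_matrix
from elicitopt.metrics import evaluate
from elicitopt.pipeline import MODEL_ORDER, split_train_test_matrix

OUT = Path("results")
SEED = 0


def main() -> None:
    rows = []
    for elicitor in ("CE", "CF", "CW"):
        dm = to_design_matrix(
            read_experiment_csv(OUT / f"synthetic_{elicitor.lower()}.csv"),
            elicitor)
        split = split_train_test_matrix(dm.n, 0.75, SEED)
        tr, te = list(split.train_indices), list(split.test_indices)
        preds = {name: m.predict
                 for name, m in fit_all(dm.X[tr], dm.y[tr]).items()}
        anfis = train_hybrid(AnfisConfig(seed=SEED), dm.X[tr], dm.y[tr])
        preds["ANFIS"] = lambda Z, m=anfis: predict(np.atleast_2d(Z), m)
        for name in MODEL_ORDER:
            for subset, idx in (("train", tr), ("test", te)):
                fm = evaluate(preds[name](dm.X[idx]), dm.y[idx])
                rows.append({"elicitor": elicitor, "model": name,
                             "subset": subset, "r2": fm.r2, "rmse": fm.rmse,
                             "mae": fm.mae, "p_overall": fm.p_overall})
    df = pd.DataFrame(rows)
    df.round(4).to_csv(OUT / "model_comparison.csv", index=False)
    wide = df.query("subset == 'test'").pivot(index="model",
                                              columns="elicitor", values="r2")
    print("test-subset R^2 per model:")
    print(wide.round(2).to_string())
    print(f"\nwrote {OUT / 'model_comparison.csv'}")


if __name__ == "__main__":
    main()
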