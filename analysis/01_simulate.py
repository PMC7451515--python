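#!/usr/bin/env python
"""Generate the synthetic factorial elicitation datasets.

Writes one CSV per elicitor type (CE, CF, CW) with the full randomized
complete block design — doses 0/1/2.5/5/10 % v/v, MBCD 0/50 mM, elicitor
adding on day 13 or 17, harvests every 2 days until day 23, three blocks —
and noisy responses from the known ground-truth surface.  Prints the row
counts and the noiseless optimum the later steps try to recover.
"""

from pathlib import Path

from elicitopt.data_model import write_experiment_csv
from elicitopt.synthetic import (DesignSpec, SyntheticSurfaceSpec,
                                 generate_dataset, true_optimum)

OUT = Path("results")
SEED = 0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    design, surface = DesignSpec(), SyntheticSurfaceSpec()
    for i, elicitor in enumerate(("CE", "CF", "CW")):
        table = generate_dataset(design, surface, seed=SEED + i,
                                 elicitor=elicitor)
        path = OUT / f"synthetic_{elicitor.lower()}.csv"
        write_experiment_csv(table, path)
        print(f"{elicitor}: wrote {len(table)} rows to {path}")
    pt, val = true_optimum()
    print(f"ground-truth optimum: conc={pt[0]:.2f} % v/v, MBCD={pt[1]:.1f} mM, "
          f"adding day {pt[2]:.1f}, harvest day {pt[3]:.2f} "
          f"-> {val:.1f} ug/l (noiseless)")


if __name__ == "__main__":
    main()
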