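"""Predictive performance on dataset 2 (no group effect) and dataset 3 (n=262).

Same protocol as the dataset-1 driver; dataset 2 excludes the random
factor from the predictive models (it does not act on the phenotype
there), dataset 3 keeps it.

Usage: python analysis/04_prediction_other_datasets.py [--reps 10] [--seed 1]
"""

import argparse
import time
from pathlib import Path

from mbpredict.pipelines import run_simulation_study
from mbpredict.synthetic import SimulationConfig

ap = argparse.ArgumentParser()
ap.add_argument("--reps", type=int, default=10)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--config-dir", type=Path, default=Path("results"))
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

for ds, include_random in (("2", False), ("3", True)):
    cfg = SimulationConfig.load(args.config_dir / f"config_dataset{ds}.yaml")
    t0 = time.time()
    tables = run_simulation_study(
        cfg, reps=args.reps, models=("tpnb",), transforms=("asin",),
        strategies=("lasso", "screen_glm", "screen_lasso"),
        include_random=include_random, with_oracle=True, seed=args.seed,
    )
    args.out.mkdir(parents=True, exist_ok=True)
    tables["prediction"].to_csv(args.out / f"prediction_dataset{ds}.tsv",
                                sep="\t", index=False)
    tables["prediction_summary"].to_csv(
        args.out / f"prediction_dataset{ds}_summary.tsv", sep="\t", index=False)
    print(f"dataset {ds} done in {time.time()-t0:.0f}s")
    print(tables["prediction_summary"].round(3).to_string(index=False), "\n")
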