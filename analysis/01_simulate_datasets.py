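#!/usr/bin/env python
"""Generate the four standard synthetic studies and write them as CSV + YAML.

Products (under results/data/):
  calibration_acetic.csv  — 10-concentration series x 24 replicates, 0.5% noise
  mixture_grid.csv        — 25 mixed-acid classes (acetic fixed at 6 mmol/L)
  spirit_population.csv   — 12 fingerprint classes x 24 replicates
  adulteration_blends.csv — 50-90% volumetric blends of two spirit fingerprints
"""

import argparse
from pathlib import Path

from csarray import datasets, pipeline

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

calib = pipeline.synthetic_calibration_set("acetic", seed=args.seed)
datasets.write_response_set(args.out / "calibration_acetic.csv", calib)
print(f"calibration_acetic.csv: {len(calib)} rows, replicate sd {calib.metadata['replicate_sd']:.3f}")

grid = pipeline.synthetic_mixture_grid_set(args.seed)
datasets.write_response_set(args.out / "mixture_grid.csv", grid)
print(f"mixture_grid.csv: {len(grid)} rows, {grid.labels['label'].nunique()} classes")

pop = pipeline.synthetic_spirit_population(args.seed)
datasets.write_response_set(args.out / "spirit_population.csv", pop)
print(f"spirit_population.csv: {len(pop)} rows, {pop.labels['label'].nunique()} classes")

_, genuine, blends = pipeline.synthetic_adulteration_study(args.seed)
datasets.write_response_set(args.out / "adulteration_blends.csv", blends)
fractions = [float(f) for f in sorted(blends.labels["fraction"].unique())]
print(f"adulteration_blends.csv: {len(blends)} rows at fractions {fractions}")
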