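"""Simulate the two synthetic study cohorts used by the downstream analyses.

Writes to results/:
  repeatability_exams.csv — 13 patients, both eyes, triplicate same-visit
      testing (test 1 is the learning test), mid-stage RP preset.
  longitudinal_exams.csv  — 14 patients, both eyes, one test at each of two
      visits a year apart, mid-stage preset with progression.
  late_stage_exams.csv    — 13 patients, late-stage preset, used to study
      the mean-sensitivity floor effect.
"""

import argparse
from pathlib import Path

import numpy as np

from microrep import NoiseModel, build_grid_10_2, save_exams, simulate_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--out-dir", default="results")
args = parser.parse_args()

out = Path(args.out_dir)
out.mkdir(exist_ok=True)
grid = build_grid_10_2()
noise = NoiseModel()

cohorts = {
    "repeatability_exams.csv": simulate_cohort(
        13, "mid", noise, design="triplicate", seed=args.seed, grid=grid),
    "longitudinal_exams.csv": simulate_cohort(
        14, "mid", noise, design="two_visit", follow_up_years=1.0,
        seed=args.seed + 1, grid=grid),
    "late_stage_exams.csv": simulate_cohort(
        13, "late", noise, design="triplicate", seed=args.seed + 2, grid=grid),
}
for name, exams in cohorts.items():
    save_exams(exams, grid, out / name)
    vals = np.concatenate([e.values(grid) for e in exams])
    print(f"{name}: {len(exams)} exams, "
          f"{100 * np.mean(vals == -1.0):.1f}% non-seen loci")
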