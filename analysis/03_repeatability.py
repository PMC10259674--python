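"""Test-retest repeatability of the three indices on the triplicate cohort.

For each eye: Bland-Altman bias, limits of agreement and CoR — mixed-model
(patient random intercept) for the clustered pointwise series, naive for
the one-value-per-patient global indices — with patient-level bootstrap
CIs, plus Wilcoxon signed-rank tests of test2 vs test3 with Holm
adjustment.  Writes results/bland_altman.csv, results/wilcoxon.csv and
results/bland_altman_pointwise.png.
"""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from microrep import (build_grid_10_2, cor_by_eye, load_exams, make_pairs,
                      paired_wilcoxon, adjust_pvalues, round_cor_convention)
from microrep.repeatability import (UndefinedStatisticError, ba_results_frame,
                                    global_series, pointwise_series)
from microrep.viz import bland_altman_plot

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--boot", type=int, default=1000)
parser.add_argument("--out-dir", default="results")
args = parser.parse_args()

out = Path(args.out_dir)
grid = build_grid_10_2()
exams = load_exams(out / "repeatability_exams.csv", grid)
pairs = make_pairs(exams, "test2_vs_test3")
print(f"{len(pairs)} test pairs (test 1 treated as a learning test)")

frames, wilcox_rows = [], []
for index in ("pointwise", "mean_sensitivity", "volume_sensitivity"):
    res = cor_by_eye(pairs, index, grid, n_boot=args.boot, seed=args.seed)
    frames.append(ba_results_frame(res, index))
    for eye, r in res.items():
        unit = "dB*deg2" if index == "volume_sensitivity" else "dB"
        print(f"  {index:18s} {eye:5s}: CoR ±{r.cor:8.2f} {unit} "
              f"(bias {r.bias:+.2f}, LoA [{r.loa_lower:.2f}, {r.loa_upper:.2f}], "
              f"{r.method})")
    # paired test2-vs-test3 comparison per eye, adjusted as one family below
    for eye in res:
        eye_pairs = [p for p in pairs if p.eye == eye]
        s = (pointwise_series(eye_pairs, grid) if index == "pointwise"
             else global_series(eye_pairs, index, grid))
        try:
            t = paired_wilcoxon(s.values_a, s.values_b)
            wilcox_rows.append({"index": index, "eye": eye,
                                "statistic": t.statistic, "p_raw": t.p_raw})
        except UndefinedStatisticError:
            wilcox_rows.append({"index": index, "eye": eye,
                                "statistic": None, "p_raw": None})

ba = pd.concat(frames, ignore_index=True)
ba.to_csv(out / "bland_altman.csv", index=False)

wx = pd.DataFrame(wilcox_rows)
wx["p_holm"] = adjust_pvalues(wx["p_raw"].values, "holm")
wx.to_csv(out / "wilcoxon.csv", index=False)
n_sig = int((wx["p_holm"] <= 0.05).sum())
print(f"Wilcoxon test2 vs test3: {n_sig}/{len(wx)} comparisons significant "
      "after Holm adjustment (expect ~0: same latent field)")

ptw = ba[ba["index"] == "pointwise"]
cut = round_cor_convention(float(ptw["cor"].max()))
print(f"pointwise CoR rounded down for the endpoint cutoff: ±{cut:.0f} dB")

fig, axes = plt.subplots(1, 2, figsize=(10, 4))
res = cor_by_eye(pairs, "pointwise", grid, n_boot=0)
for ax, (eye, r) in zip(axes, res.items()):
    s = pointwise_series([p for p in pairs if p.eye == eye], grid)
    bland_altman_plot(s, r, ax=ax, title=f"pointwise test2 vs test3 ({eye})")
fig.tight_layout()
fig.savefig(out / "bland_altman_pointwise.png", dpi=150)
print(f"wrote {out/'bland_altman.csv'}, {out/'wilcoxon.csv'} and plot")
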