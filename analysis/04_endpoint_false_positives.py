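"""False-positive probability of the k-of-n pointwise endpoint.

By the CoR's definition a repeat test exceeds the +/-CoR band at 5% of
loci by chance.  This script tabulates P(>= 5 loci exceed | n loci tested)
for the full 68-locus grid and the central 36/16 subsets, verifies the
analytic binomial tail against a Monte-Carlo simulation, and shows how the
false-positive rate varies with the cluster size k.  Writes
results/endpoint_false_positives.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from microrep import endpoint_false_positive_prob, monte_carlo_endpoint_check

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--n-sim", type=int, default=100_000)
parser.add_argument("--out-dir", default="results")
args = parser.parse_args()

rows = []
for region, n in (("all68", 68), ("central36", 36), ("central16", 16)):
    analytic = endpoint_false_positive_prob(n, 5, 0.05)
    mc = monte_carlo_endpoint_check(n, 5, 0.05, args.n_sim, seed=args.seed)
    rows.append({"region": region, "n_loci": n, "min_loci": 5,
                 "per_point_prob": 0.05, "analytic": analytic,
                 "monte_carlo": mc})
    print(f"P(>=5 of {n:2d} loci exceed ±CoR by chance) = {100 * analytic:6.2f}% "
          f"(Monte-Carlo {100 * mc:6.2f}%)")

print("\nfalse-positive rate vs required cluster size (n=68):")
for k in range(1, 11):
    p = endpoint_false_positive_prob(68, k, 0.05)
    rows.append({"region": "all68", "n_loci": 68, "min_loci": k,
                 "per_point_prob": 0.05, "analytic": p, "monte_carlo": None})
    print(f"  k={k:2d}: {100 * p:7.3f}%")

out = Path(args.out_dir)
out.mkdir(exist_ok=True)
pd.DataFrame(rows).to_csv(out / "endpoint_false_positives.csv", index=False)
print(f"\nRestricting the endpoint to the central 16 loci cuts the chance "
      "of a spurious 5-locus cluster from ~25% to ~0.1%.")
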