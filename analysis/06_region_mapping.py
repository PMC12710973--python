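#!/usr/bin/env python
"""Region-resolved stress: CPD registration onto fluorescence-defined zones.

Builds the two-region tumor scenario (fluorescence-positive regions at
3.5 +/- 2.8 kPa, negative regions at 7.4 +/- 2.8 kPa), runs the full
chain -- render, detect, invert, non-rigid CPD registration of the MR
surface onto the fluorescence surface, sensor transfer, region assignment
-- and reports the recovered per-region stress statistics.  Writes
``results/region_stats.csv``.
"""

import argparse
from pathlib import Path

import pandas as pd

from mechanomap.benchmarks import two_region_recovery


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-per-region", type=int, default=60)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    res = two_region_recovery(args.seed, n_per_region=args.n_per_region)
    pd.DataFrame([res]).to_csv(args.out / "region_stats.csv", index=False)
    print(f"fluorescence-positive regions: {res['positive_mean_kPa']:.2f} kPa "
          f"(n={res['positive_n']}, generating mean 3.5)")
    print(f"fluorescence-negative regions: {res['negative_mean_kPa']:.2f} kPa "
          f"(n={res['negative_n']}, generating mean 7.4)")
    print(f"difference {res['negative_mean_kPa'] - res['positive_mean_kPa']:.2f} kPa; "
          f"CPD converged: {res['cpd_converged']}")


if __name__ == "__main__":
    main()
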