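#!/usr/bin/env python
"""Single-particle signal quality on a zero-stress calibration phantom.

Renders a 30-particle zero-stress phantom at the default noise level,
detects every particle, and reports the per-particle contrast-to-noise
ratio (SNR) and the repeat-measurement coefficient of variation of SBR
over 10 independent noise realizations of the same phantom geometry.
Writes ``results/phantom_quality.csv``.
"""

import argparse
from pathlib import Path

import pandas as pd

from mechanomap.benchmarks import phantom_sbr_cv, phantom_snr


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    snr = phantom_snr(args.seed)
    cv = phantom_sbr_cv(args.seed)
    df = pd.DataFrame([
        {"metric": "mean_single_particle_snr", "value": snr["snr"], "n": snr["n"]},
        {"metric": "sbr_cv_percent", "value": cv["cv_percent"], "n": cv["n"]},
    ])
    df.to_csv(args.out / "phantom_quality.csv", index=False)
    print(df.to_string(index=False))
    print(f"\n{snr['n']}/30 particles detected; SNR {snr['snr']:.2f} "
          f"(design target 9.5), repeat-measurement CV {cv['cv_percent']:.2f}% "
          f"over {cv['realizations']} noise realizations")


if __name__ == "__main__":
    main()
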