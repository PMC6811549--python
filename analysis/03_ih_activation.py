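#!/usr/bin/env python
"""I_h activation: per-cell Boltzmann midpoints from the voltage-clamp
step protocol (-50 mV holding, -10 mV steps, 5 s).

Expected pattern: knockout midpoints hyperpolarised by ~6 mV with a
similar maximal current (normal channel complement, shifted gating).
"""

import argparse
from pathlib import Path

from spinequant.io import read_cohort
from spinequant.pipeline import stage_ih


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.h5"))
    ap.add_argument("--out", type=Path, default=Path("results/ih.csv"))
    args = ap.parse_args()

    table = stage_ih(read_cohort(args.cohort))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(f"wrote {len(table)} cells to {args.out}")
    print(table.groupby("genotype")[["v12_mv", "k_mv", "ih_at_deepest_pa"]]
          .mean().round(2).to_string())


if __name__ == "__main__":
    main()
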