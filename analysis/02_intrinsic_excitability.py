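#!/usr/bin/env python
"""Intrinsic excitability: input resistance, rheobase, sag/rebound and
chirp resonance per cell, with genotype group means.

Expected pattern: the knockout has higher input resistance and reduced
sag/rebound (less HCN current active near rest), with its activation
midpoint shifted — the direct measurement of which is analysis 03.
"""

import argparse
from pathlib import Path

from spinequant.io import read_cohort
from spinequant.pipeline import stage_intrinsic


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.h5"))
    ap.add_argument("--out", type=Path, default=Path("results/intrinsic.csv"))
    args = ap.parse_args()

    table = stage_intrinsic(read_cohort(args.cohort))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(f"wrote {len(table)} cells to {args.out}")
    cols = ["r_input_mohm", "rheobase_pa", "sag_pct", "rebound_slope",
            "f_res_hz", "q_factor"]
    print(table.groupby("genotype")[cols].mean().round(2).to_string())


if __name__ == "__main__":
    main()
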