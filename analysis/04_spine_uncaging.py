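#!/usr/bin/env python
"""Single-spine glutamate uncaging: AMPA/NMDA uEPSC amplitudes, silent
spine calls and NMDA/AMPA ratios.

Expected pattern: larger uEPSCs and a roughly threefold higher silent-
spine fraction in the knockout, with an elevated NMDA/AMPA ratio.
"""

import argparse
from pathlib import Path

from spinequant.io import read_cohort
from spinequant.pipeline import stage_uncage_seq


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.h5"))
    ap.add_argument("--out", type=Path, default=Path("results/uncage_seq.csv"))
    args = ap.parse_args()

    table = stage_uncage_seq(read_cohort(args.cohort))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(f"wrote {len(table)} spines to {args.out}")
    resp = table[table.call == "responsive"]
    print("responsive uEPSC (pA):",
          resp.groupby("genotype")["ampa_amp_pa"].mean().round(2).to_dict())
    print("NMDA/AMPA ratio:",
          resp.groupby("genotype")["ratio"].mean().round(2).to_dict())
    silent = table.groupby("genotype").apply(
        lambda g: (g.call == "silent").sum()
        / max((g.call != "unresponsive").sum(), 1),
        include_groups=False)
    print("silent fraction:", silent.round(3).to_dict())


if __name__ == "__main__":
    main()
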