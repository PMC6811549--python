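#!/usr/bin/env python
"""Hierarchical genotype comparisons of every extracted feature table:
linear mixed models with litter/animal/slice random intercepts, tested
by likelihood ratio against the genotype-free model.
"""

import argparse
from pathlib import Path

import pandas as pd

from spinequant.pipeline import compare_genotypes


FEATURES = [
    ("intrinsic.csv", "r_input_mohm"),
    ("intrinsic.csv", "sag_pct"),
    ("intrinsic.csv", "f_res_hz"),
    ("ih.csv", "v12_mv"),
    ("uncage_seq.csv", "ampa_amp_pa"),
    ("uncage_seq.csv", "ratio"),
    ("uncage_multi.csv", "spines_to_ap"),
    ("mepsc.csv", "frequency_hz"),
]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    rows = []
    for fname, col in FEATURES:
        path = args.results / fname
        if not path.exists():
            print(f"skipping {fname}:{col} (table missing)")
            continue
        table = pd.read_csv(path)
        if fname == "uncage_seq.csv":
            table = table[table.call == "responsive"]
        if fname == "mepsc.csv":
            table = table[table.receptor == "nmda"]
        try:
            res = compare_genotypes(table, col)
        except (ValueError, RuntimeError) as exc:
            print(f"{fname}:{col}: comparison failed ({exc})")
            continue
        rows.append(dict(table=fname, feature=col, method=res.method,
                         statistic=round(res.statistic, 3),
                         p_value=res.p_value, direction=res.direction,
                         family=res.meta.get("family")))
    out = pd.DataFrame(rows)
    out.to_csv(args.results / "comparisons.csv", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
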