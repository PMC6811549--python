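#!/usr/bin/env python
"""Generate the synthetic wild-type / Fmr1-knockout cohort.

Every downstream analysis reads the HDF5 sweep table written here.  The
default size (3 animals x 2 cells per genotype, all protocols) keeps the
full pipeline to a couple of minutes while leaving >= 2 animals per
genotype for the nested statistics.
"""

import argparse
from pathlib import Path

from spinequant.cohort import generate_cohort
from spinequant.io import write_cohort


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-animals", type=int, default=3)
    ap.add_argument("--cells-per-animal", type=int, default=2)
    ap.add_argument("--out", type=Path, default=Path("results/cohort.h5"))
    args = ap.parse_args()

    cohort = generate_cohort(n_animals=args.n_animals,
                             cells_per_animal=args.cells_per_animal,
                             seed=args.seed)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, args.out)
    n_sweeps = sum(len(s) for c in cohort for s in c.sweeps.values())
    print(f"wrote {len(cohort)} cells ({n_sweeps} sweeps) to {args.out}")
    for geno in cohort.genotypes():
        cells = cohort.by_genotype(geno)
        animals = {c.animal_id for c in cells}
        print(f"  {geno}: {len(cells)} cells from {len(animals)} animals")


if __name__ == "__main__":
    main()
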