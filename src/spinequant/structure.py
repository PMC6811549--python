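"""Summary-level spine morphology and ultrastructure statistics.

All group summaries aggregate per animal first and only then across
animals; pooled-spine statistics are never silently substituted (the
mouse, not the spine, is the experimental unit).  Image processing is
upstream: these operations start from measurement tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import curve_compare_ftest, ComparisonResult

log = logging.getLogger(__name__)


def morph_summary(spines: pd.DataFrame) -> pd.DataFrame:
    """Per-animal mean head width, neck length and spine density.

    ``spines`` has one row per spine with columns ``animal_id``,
    ``genotype``, ``head_width_um``, ``neck_length_um`` and optionally
    ``dendrite_um`` (dendritic length sampled; density is spines per
    10 um and is omitted when lengths are absent).  Rows without an
    animal id are excluded with a log entry.
    """
    df = spines.copy()
    bad = df["animal_id"].isna() | (df["animal_id"] == "")
    if bad.any():
        log.warning("excluding %d spines without animal_id", int(bad.sum()))
        df = df[~bad]
    if df.empty:
        raise ValueError("no spines with animal metadata")
    rows = []
    for (animal, geno), grp in df.groupby(["animal_id", "genotype"]):
        row = dict(animal_id=animal, genotype=geno, n_spines=len(grp),
                   head_width_um=float(grp["head_width_um"].mean()),
                   neck_length_um=float(grp["neck_length_um"].mean()))
        if "dendrite_um" in grp and grp["dendrite_um"].notna().all():
            # density = spines per 10 um of the sampled dendrite; each row
            # carries the length of the dendrite it was sampled from
            dend_len = grp["dendrite_um"].iloc[0]
            row["density_per_10um"] = len(grp) / dend_len * 10.0
        rows.append(row)
    return pd.DataFrame(rows)


def structure_function(spines: pd.DataFrame,
                       x: str = "head_width_um",
                       y: str = "ampa_amp_pa"):
    """Per-genotype structure-function regression and slope-equality test.

    Ordinary least squares of uEPSC amplitude on the morphological
    variable per genotype (responsive, uncaged spines only; pooled across
    animals as in the source analysis), plus a sum-of-squares F-test of
    slope equality between genotypes.

    Returns (per_genotype: dict genotype -> (slope, intercept, r2, n),
    comparison: ComparisonResult).
    """
    df = spines.dropna(subset=[x, y])
    out = {}
    for geno, grp in df.groupby("genotype"):
        if len(grp) < 3:
            raise ValueError(f"genotype {geno}: need >= 3 linked spines")
        coeffs = np.polyfit(grp[x], grp[y], 1)
        pred = np.polyval(coeffs, grp[x])
        ss_res = float(np.sum((grp[y] - pred) ** 2))
        ss_tot = float(np.sum((grp[y] - grp[y].mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        out[str(geno)] = (float(coeffs[0]), float(coeffs[1]), r2, len(grp))

    def line(xv, a, b):
        return a * xv + b

    comp = curve_compare_ftest(df[x].to_numpy(), df[y].to_numpy(),
                               df["genotype"].to_numpy(), line, p0=[1.0, 0.0])
    return out, comp


def mis_incidence(records: pd.DataFrame):
    """Per-animal multi-innervated-spine incidence (%) and group means.

    ``records`` has one row per dendrite with ``n_spines`` and ``n_mis``.
    Incidence per animal = sum(n_mis) / sum(n_spines) * 100; animals with
    zero spines are excluded.  Returns (per_animal DataFrame, group
    means dict genotype -> mean %).
    """
    rows = []
    for (animal, geno), grp in records.groupby(["animal_id", "genotype"]):
        tot = int(grp["n_spines"].sum())
        if tot == 0:
            log.warning("excluding animal %s with zero spines", animal)
            continue
        mis = int(grp["n_mis"].sum())
        if not (0 <= mis <= tot):
            raise ValueError(f"animal {animal}: n_mis outside [0, n_spines]")
        rows.append(dict(animal_id=animal, genotype=geno,
                         n_spines=tot, n_mis=mis,
                         incidence_pct=100.0 * mis / tot))
    per_animal = pd.DataFrame(rows)
    if per_animal.empty:
        raise ValueError("no animals with spines")
    group = {str(g): float(grp["incidence_pct"].mean())
             for g, grp in per_animal.groupby("genotype")}
    return per_animal, group
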