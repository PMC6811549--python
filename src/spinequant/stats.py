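"""Group-level statistics: distribution-family selection, hierarchical
(nested) genotype comparison by likelihood-ratio test, sum-of-squares
F-tests for regression comparison, and normality-gated exact/rank tests.

The hierarchical comparison mirrors the experimental design: genotype (plus
optionally drug and their interaction) as fixed effects and litter /
animal / slice as nested random intercepts; significance comes from a
likelihood-ratio test against the model with the term of interest
dropped.  Log-normal and gamma families are handled as linear mixed
models on log-transformed values (recorded in the result metadata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_NORMALITY = 0.05


@dataclass
class ComparisonResult:
    method: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    direction: float = 0.0  # sign of the effect (group2 - group1)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# distribution-family selection
# ---------------------------------------------------------------------------

def select_family(values) -> str:
    """Pick {normal, log-normal, gamma} by maximum likelihood.

    All three candidates have two free parameters (location fixed at zero
    for the positive-support families), so the ML comparison coincides
    with AIC.  Non-positive values restrict the choice to normal.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 8:
        raise ValueError("need n >= 8 values for family selection")
    if np.ptp(x) == 0:
        raise ValueError("constant values: family selection is degenerate")
    if np.any(x <= 0):
        return "normal"
    ll = {}
    mu, sd = x.mean(), x.std(ddof=0)
    ll["normal"] = float(np.sum(sps.norm.logpdf(x, mu, sd)))
    lx = np.log(x)
    ll["log-normal"] = float(
        np.sum(sps.norm.logpdf(lx, lx.mean(), lx.std(ddof=0)) - lx))
    a, _, scale = sps.gamma.fit(x, floc=0)
    ll["gamma"] = float(np.sum(sps.gamma.logpdf(x, a, 0, scale)))
    return max(ll, key=ll.get)


# ---------------------------------------------------------------------------
# hierarchical genotype comparison (LMM + LRT)
# ---------------------------------------------------------------------------

def hierarchical_compare(values, genotype, animal,
                         litter=None, slice_=None,
                         family: str = "normal",
                         drug=None) -> ComparisonResult:
    """Mixed-model comparison of genotypes with nested random intercepts.

    Random intercepts for litter, animal and slice; a level is dropped
    automatically (slice first, then litter, never animal) when it has
    fewer than 2 groups or when the fit is singular, and the
    simplification is recorded in the result metadata.  The p-value is a
    likelihood-ratio test of the genotype fixed effect (ML fits).
    """
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "genotype": pd.Categorical(genotype),
        "animal": [str(a) for a in animal],
    })
    if litter is not None:
        df["litter"] = [str(x) for x in litter]
    if slice_ is not None:
        df["slice"] = [str(x) for x in slice_]
    if drug is not None:
        df["drug"] = pd.Categorical(drug)
    if df["genotype"].nunique() != 2:
        raise ValueError("exactly two genotype levels are required")
    for g in df["genotype"].cat.categories:
        if df.loc[df.genotype == g, "animal"].nunique() < 2:
            raise ValueError(f"genotype {g}: need >= 2 animals")

    transformed = family in ("log-normal", "gamma")
    if transformed:
        if np.any(df["y"] <= 0):
            raise ValueError(f"{family} family requires positive values")
        df["y"] = np.log(df["y"])

    fixed_full = "y ~ genotype" + (" + drug + genotype:drug" if drug is not None else "")
    fixed_red = "y ~ 1" + (" + drug" if drug is not None else "")

    use_slice = "slice" in df and df["slice"].nunique() > 1
    use_litter = "litter" in df and 1 < df["litter"].nunique() < df["animal"].nunique()

    attempts = []
    for try_slice, try_litter in [(use_slice, use_litter),
                                  (False, use_litter), (False, False)]:
        attempts.append((try_slice, try_litter))
    tried = set()
    last_exc: Exception | None = None
    for try_slice, try_litter in attempts:
        key = (try_slice, try_litter)
        if key in tried:
            continue
        tried.add(key)
        groups = df["litter"] if try_litter else df["animal"]
        vc: dict[str, str] = {}
        if try_litter:
            vc["animal"] = "0 + C(animal)"
        if try_slice:
            vc["slice"] = "0 + C(slice)"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = smf.mixedlm(fixed_full, df, groups=groups,
                                   vc_formula=vc or None).fit(reml=False)
                red = smf.mixedlm(fixed_red, df, groups=groups,
                                  vc_formula=vc or None).fit(reml=False)
            if not (np.isfinite(full.llf) and np.isfinite(red.llf)):
                raise RuntimeError("non-finite log-likelihood")
        except Exception as exc:  # singular fit etc.: simplify and retry
            last_exc = exc
            continue
        stat = 2.0 * (full.llf - red.llf)
        ddf = full.df_modelwc - red.df_modelwc
        stat = max(stat, 0.0)
        p = float(sps.chi2.sf(stat, max(ddf, 1)))
        geno_terms = [t for t in full.params.index
                      if t.startswith("genotype[") and ":" not in t]
        direction = float(np.sign(full.params[geno_terms[0]])) if geno_terms else 0.0
        return ComparisonResult(
            method="LMM/LRT" if not transformed else f"LMM/LRT(log,{family})",
            statistic=float(stat), p_value=p, df=float(max(ddf, 1)),
            direction=direction,
            meta=dict(family=family,
                      random_effects={
                          "litter": try_litter, "animal": True,
                          "slice": try_slice},
                      simplified=(try_slice, try_litter) != attempts[0],
                      fixed_effect=geno_terms[0] if geno_terms else None,
                      coef=float(full.params[geno_terms[0]]) if geno_terms else None))
    raise RuntimeError(f"mixed model failed at all simplification levels: {last_exc}")


# ---------------------------------------------------------------------------
# sum-of-squares F-test for nested regressions
# ---------------------------------------------------------------------------

def f_test_nested(ss_shared: float, df_shared: float,
                  ss_separate: float, df_separate: float) -> ComparisonResult:
    """F-test of a shared-parameter fit against per-group fits."""
    if ss_separate <= 0:
        raise ValueError("separate-fit SSE is zero: F-test degenerate")
    if df_shared <= df_separate:
        raise ValueError("models are not nested (df_shared must exceed df_separate)")
    f = ((ss_shared - ss_separate) / (df_shared - df_separate)) / (
        ss_separate / df_separate)
    f = max(f, 0.0)
    p = float(sps.f.sf(f, df_shared - df_separate, df_separate))
    return ComparisonResult(method="SS F-test", statistic=float(f), p_value=p,
                            df=(float(df_shared - df_separate),
                                float(df_separate)))


def curve_compare_ftest(x, y, groups, model, p0,
                        bounds=(-np.inf, np.inf)) -> ComparisonResult:
    """Fit ``model(x, *params)`` shared across groups vs separately per
    group and compare by sum-of-squares F-test."""
    from scipy.optimize import curve_fit

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = len(p0)

    def sse_of(xs, ys):
        popt, _ = curve_fit(model, xs, ys, p0=p0, bounds=bounds, maxfev=20000)
        return float(np.sum((model(xs, *popt) - ys) ** 2))

    ss_shared = sse_of(x, y)
    df_shared = len(x) - k
    ss_sep = sum(sse_of(x[groups == g], y[groups == g]) for g in labels)
    df_sep = len(x) - k * len(labels)
    if len(labels) < 2:
        return ComparisonResult(method="SS F-test", statistic=0.0,
                                p_value=1.0, df=(0.0, float(df_shared)))
    return f_test_nested(ss_shared, df_shared, ss_sep, df_sep)


# ---------------------------------------------------------------------------
# exact and rank tests with normality gate
# ---------------------------------------------------------------------------

def exact_and_rank_tests(x, y=None, design: str = "unpaired",
                         table=None) -> ComparisonResult:
    """Normality-gated two-sample tests and Fisher's exact test.

    unpaired: d'Agostino-Pearson on both groups (alpha = 0.05); both
    normal -> Student's t, otherwise Mann-Whitney U.  paired: gate on the
    differences; paired t vs Wilcoxon signed-rank.  contingency: 2x2
    Fisher's exact, two-sided by the point-probability rule.
    """
    if design == "contingency":
        tab = np.asarray(table if table is not None else x)
        if tab.shape != (2, 2):
            raise ValueError("contingency design requires a 2x2 table")
        odds, p = sps.fisher_exact(tab, alternative="two-sided")
        return ComparisonResult(method="Fisher exact", statistic=float(odds),
                                p_value=float(p),
                                direction=float(np.sign(np.log(odds)))
                                if 0 < odds < np.inf else 0.0)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if design == "unpaired":
        normal = (sps.normaltest(x).pvalue > ALPHA_NORMALITY
                  and sps.normaltest(y).pvalue > ALPHA_NORMALITY)
        if normal:
            r = sps.ttest_ind(x, y)
            return ComparisonResult(method="t-test", statistic=float(r.statistic),
                                    p_value=float(r.pvalue),
                                    df=float(len(x) + len(y) - 2),
                                    direction=float(np.sign(y.mean() - x.mean())))
        r = sps.mannwhitneyu(x, y, alternative="two-sided")
        return ComparisonResult(method="Mann-Whitney U",
                                statistic=float(r.statistic),
                                p_value=float(r.pvalue),
                                direction=float(np.sign(np.median(y) - np.median(x))))
    if design == "paired":
        if len(x) != len(y):
            raise ValueError("paired design requires equal lengths")
        d = y - x
        normal = sps.normaltest(d).pvalue > ALPHA_NORMALITY
        if normal:
            r = sps.ttest_rel(x, y)
            return ComparisonResult(method="paired t-test",
                                    statistic=float(r.statistic),
                                    p_value=float(r.pvalue),
                                    df=float(len(x) - 1),
                                    direction=float(np.sign(d.mean())))
        r = sps.wilcoxon(x, y)
        return ComparisonResult(method="Wilcoxon signed-rank",
                                statistic=float(r.statistic),
                                p_value=float(r.pvalue),
                                direction=float(np.sign(np.median(d))))
    raise ValueError(f"unknown design {design!r}")
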