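"""Statistical layer: family selection, mixed-model LRT calibration,
nested-regression F-tests and normality-gated exact/rank tests."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from spinequant.stats import (ComparisonResult, curve_compare_ftest,
                              exact_and_rank_tests, f_test_nested,
                              hierarchical_compare, select_family)


class TestSelectFamily:
    def test_normal_samples_recognised(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(10.0, 1.0, 200)
            hits += select_family(x) == "normal"
        assert hits >= 18

    def test_lognormal_samples_recognised(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).lognormal(1.0, 0.8, 200)
            hits += select_family(x) == "log-normal"
        assert hits >= 18

    def test_gamma_samples_recognised(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).gamma(2.0, 3.0, 400)
            hits += select_family(x) in ("gamma", "log-normal")
        assert hits >= 18

    def test_constant_vector_degenerate(self):
        with pytest.raises(ValueError):
            select_family(np.full(20, 3.0))

    def test_non_positive_forces_normal(self):
        x = np.concatenate([np.random.default_rng(0).normal(0, 1, 50)])
        assert select_family(x) == "normal"


def _null_dataset(rng, n_animals=10, cells=5, effect=0.0):
    values, geno, animal, litter = [], [], [], []
    for g_i, g in enumerate(("WT", "KO")):
        for a in range(n_animals):
            animal_effect = rng.normal(0, 0.5)
            for _ in range(cells):
                values.append(rng.normal(g_i * effect + animal_effect, 1.0))
                geno.append(g)
                animal.append(f"{g}{a}")
                litter.append(f"L{a}")
    return np.array(values), geno, animal, litter


class TestHierarchicalCompare:
    def test_detects_genotype_shift(self):
        rng = np.random.default_rng(42)
        v, g, a, l = _null_dataset(rng, effect=1.5)
        res = hierarchical_compare(v, g, a, litter=l)
        assert res.p_value < 0.01
        assert res.direction != 0.0

    def test_type_one_error_calibrated(self):
        """Null rejection rate within [0.025, 0.075] at alpha 0.05 over
        200 simulations (animal-clustered null data)."""
        rejections = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(1000 + seed)
            v, g, a, l = _null_dataset(rng, n_animals=10, cells=5)
            res = hierarchical_compare(v, g, a, litter=l)
            rejections += res.p_value < 0.05
        assert 0.025 <= rejections / n_sims <= 0.075

    def test_power_grows_with_animals(self):
        power = []
        for n_animals in (3, 10):
            hits = 0
            for seed in range(40):
                rng = np.random.default_rng(seed)
                v, g, a, l = _null_dataset(rng, n_animals=n_animals,
                                           cells=4, effect=0.8)
                res = hierarchical_compare(v, g, a, litter=l)
                hits += res.p_value < 0.05
            power.append(hits / 40)
        assert power[1] > power[0]

    def test_invariant_to_cell_order(self):
        rng = np.random.default_rng(7)
        v, g, a, l = _null_dataset(rng, effect=0.7)
        res1 = hierarchical_compare(v, g, a, litter=l)
        perm = np.random.default_rng(8).permutation(len(v))
        res2 = hierarchical_compare(v[perm], [g[i] for i in perm],
                                    [a[i] for i in perm],
                                    litter=[l[i] for i in perm])
        assert res1.p_value == pytest.approx(res2.p_value, rel=1e-6)

    def test_requires_two_animals_per_genotype(self):
        with pytest.raises(ValueError):
            hierarchical_compare([1.0, 2.0, 3.0, 4.0],
                                 ["WT", "WT", "KO", "KO"],
                                 ["a1", "a1", "b1", "b1"])

    def test_log_family_requires_positive(self):
        rng = np.random.default_rng(3)
        v, g, a, l = _null_dataset(rng)
        with pytest.raises(ValueError):
            hierarchical_compare(v, g, a, litter=l, family="log-normal")


class TestCurveCompare:
    def test_null_p_values_roughly_uniform(self):
        """Identical groups: fraction of p < 0.05 near nominal over 200
        linear-regression comparisons."""
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = np.tile(np.linspace(0, 1, 15), 2)
            y = 2.0 * x + rng.normal(0, 1.0, 30)
            groups = np.repeat(["a", "b"], 15)
            res = curve_compare_ftest(x, y, groups,
                                      lambda x, a, b: a * x + b, [1.0, 0.0])
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / 200 <= 0.09

    def test_separated_sigmoid_midpoints_detected(self):
        """Activation curves 6 mV apart at realistic noise separate."""
        rng = np.random.default_rng(0)
        v = np.tile(np.arange(-120.0, -55.0, 10.0), (2, 6, 1))

        def boltz(x, i_max, v12):
            return i_max / (1.0 + np.exp((x - v12) / 8.0))

        xs, ys, gs = [], [], []
        for g_i, (label, v12) in enumerate((("WT", -86.0), ("KO", -92.0))):
            for cell in range(6):
                volts = np.arange(-120.0, -55.0, 10.0)
                amps = boltz(volts, 1.0, v12) + rng.normal(0, 0.05,
                                                           len(volts))
                xs.append(volts)
                ys.append(amps)
                gs.append([label] * len(volts))
        res = curve_compare_ftest(np.concatenate(xs), np.concatenate(ys),
                                  np.concatenate(gs), boltz, [1.0, -85.0])
        assert res.p_value < 0.01

    def test_single_group_returns_zero_f(self):
        x = np.linspace(0, 1, 10)
        y = x + 0.1
        res = curve_compare_ftest(x, y, ["a"] * 10,
                                  lambda x, a, b: a * x + b, [1.0, 0.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_separate_sse_degenerate(self):
        with pytest.raises(ValueError):
            f_test_nested(1.0, 10, 0.0, 8)


def fisher_enumeration(table):
    """Independent oracle: two-sided Fisher p by exhaustive hypergeometric
    enumeration with the point-probability rule (math.comb only)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)
                / math.comb(n, c1))

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(k)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestExactAndRank:
    def test_fisher_matches_enumeration_on_connectivity_table(self):
        """Connectivity table reconstructed from 33.6 % of 110 pairs vs
        14.8 % of 54 pairs: p matches full enumeration and is significant
        at alpha = 0.05."""
        table = [[37, 73], [8, 46]]
        res = exact_and_rank_tests(None, design="contingency", table=table)
        assert res.p_value == pytest.approx(fisher_enumeration(table),
                                            rel=1e-9)
        assert res.p_value < 0.05

    def test_fisher_matches_enumeration_on_random_tables(self, rng):
        """Exact agreement with the enumeration oracle on random 2x2
        tables with totals up to 200."""
        for _ in range(60):
            tab = rng.integers(0, 51, size=(2, 2))
            if tab.sum() == 0 or tab.sum(axis=1).min() == 0:
                continue
            res = exact_and_rank_tests(None, design="contingency",
                                       table=tab)
            assert res.p_value == pytest.approx(
                fisher_enumeration(tab.tolist()), rel=1e-9, abs=1e-12)

    def test_identical_samples_mann_whitney_p_one(self):
        x = np.array([1.0, 5.0, 2.0, 8.0, 3.0, 9.0, 4.0, 2.5] * 3)
        res = exact_and_rank_tests(x, x.copy(), design="unpaired")
        if res.method == "Mann-Whitney U":
            assert res.p_value == pytest.approx(1.0, abs=0.01)
        else:  # normality gate may pick t; identical samples give p = 1
            assert res.p_value == pytest.approx(1.0, abs=0.01)

    def test_gate_selects_t_for_normal_samples(self):
        """Both groups must pass the normality gate, so the expected
        selection rate for normal data is (1 - 0.05)^2 = 90.25 %; assert
        within two binomial standard deviations (sd ~ 3 / 100 seeds)."""
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            res = exact_and_rank_tests(rng.normal(0, 1, 30),
                                       rng.normal(0, 1, 30))
            hits += res.method == "t-test"
        assert hits / 200 >= 0.9025 - 2 * 0.03

    def test_gate_selects_rank_test_for_skewed_samples(self):
        rng = np.random.default_rng(1)
        res = exact_and_rank_tests(rng.lognormal(0, 1.5, 40),
                                   rng.lognormal(0, 1.5, 40))
        assert res.method == "Mann-Whitney U"

    def test_paired_design(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 25)
        res = exact_and_rank_tests(x, x + 0.8 + rng.normal(0, 0.3, 25),
                                   design="paired")
        assert res.method in ("paired t-test", "Wilcoxon signed-rank")
        assert res.p_value < 0.01

    def test_non_2x2_contingency_rejected(self):
        with pytest.raises(ValueError):
            exact_and_rank_tests(None, design="contingency",
                                 table=np.ones((2, 3), dtype=int))

    def test_p_value_bounds_enforced(self):
        with pytest.raises(ValueError):
            ComparisonResult(method="x", statistic=0.0, p_value=1.5)
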