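"""ANOVA, Dunnett many-to-one, exact tests, ranks and power."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from neurophenopipe.stats import (anova, chi_square, dunnett,
                                  dunnett_critical_value, dunnett_tstats,
                                  fisher_exact, rank_transform, required_n)


def _tidy(groups: dict) -> pd.DataFrame:
    rows = [(g, v) for g, vals in groups.items() for v in vals]
    return pd.DataFrame(rows, columns=["group", "value"])


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    w_obs = comb(r1, a) * comb(r2, c)
    total = comb(r1 + r2, c1)
    acc = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if 10**7 * (w - w_obs) <= w_obs:  # prob <= observed (+1e-7 rel)
            acc += w
    return acc / total


class TestAnova:
    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        data = _tidy({"a": rng.normal(size=12),
                      "b": rng.normal(0.5, 1.0, size=15)})
        res = anova(data)
        t, p = spstats.ttest_ind(
            data.query("group == 'a'")["value"],
            data.query("group == 'b'")["value"])
        assert res.statistic == pytest.approx(t**2, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        data = _tidy({g: rng.normal(size=10) for g in "abc"})
        shifted = data.assign(value=data["value"] + 1234.5)
        assert anova(data).statistic == pytest.approx(
            anova(shifted).statistic, rel=1e-9)

    def test_single_level_factor_rejected(self):
        data = _tidy({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than two"):
            anova(data)

    def test_two_factor_interaction_reported(self):
        rng = np.random.default_rng(2)
        rows = [(g, tp, rng.normal()) for g in "ab" for tp in (1, 2)
                for _ in range(8)]
        data = pd.DataFrame(rows, columns=["group", "timepoint", "value"])
        res = anova(data, factors=("group", "timepoint"))
        assert len(res.table) == 4  # two mains, interaction, residual

    def test_repeated_measures_anova_runs(self):
        rng = np.random.default_rng(3)
        rows = [(s, q, rng.normal()) for s in range(8) for q in "TROL"]
        data = pd.DataFrame(rows, columns=["subject", "quadrant", "value"])
        res = anova(data, factors=("quadrant",), subject="subject")
        assert res.name == "rm-anova"
        assert 0.0 <= res.p_value <= 1.0


class TestDunnett:
    def test_single_treated_group_reduces_to_t_test(self):
        rng = np.random.default_rng(4)
        data = _tidy({"ctl": rng.normal(size=15),
                      "trt": rng.normal(0.8, 1.0, size=15)})
        res = dunnett(data, control="ctl")
        _, p = spstats.ttest_ind(
            data.query("group == 'trt'")["value"],
            data.query("group == 'ctl'")["value"])
        assert res.table["p_adj"].iloc[0] == pytest.approx(p, abs=2e-3)

    def test_adding_a_group_never_decreases_adjusted_p(self):
        rng = np.random.default_rng(5)
        base = {"ctl": rng.normal(size=15), "a": rng.normal(size=15)}
        extra = dict(base, b=rng.normal(size=15))
        p1 = dunnett(_tidy(base), control="ctl").table
        p2 = dunnett(_tidy(extra), control="ctl").table
        pa1 = p1.set_index("group").loc["a", "p_adj"]
        pa2 = p2.set_index("group").loc["a", "p_adj"]
        assert pa2 >= pa1 - 2e-3

    def test_missing_control_rejected(self):
        data = _tidy({"a": [1.0, 2.0], "b": [2.0, 3.0]})
        with pytest.raises(ValueError, match="control"):
            dunnett(data, control="ctl")

    def test_batched_tstats_match_scipy(self):
        rng = np.random.default_rng(6)
        ctl = rng.normal(size=17)
        trt = [rng.normal(size=n) for n in (15, 15, 17)]
        res = spstats.dunnett(*trt, control=ctl, random_state=0)
        mine = dunnett_tstats(ctl, trt)
        assert np.allclose(mine, res.statistic, rtol=1e-9)

    def test_critical_value_agrees_with_adjusted_p(self):
        # at t == critical value the adjusted p should equal alpha
        c = dunnett_critical_value(15, [15, 15, 15], alpha=0.05, seed=0)
        ns, n0, k = [15, 15, 15], 15, 3
        df = n0 + sum(ns) - (k + 1)
        lam = np.sqrt(np.array(ns) / (np.array(ns) + n0))
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        mvt = spstats.multivariate_t(loc=np.zeros(k), shape=corr, df=df)
        inside = mvt.cdf(c * np.ones(k), lower_limit=-c * np.ones(k),
                         random_state=np.random.default_rng(1))
        assert 1.0 - inside == pytest.approx(0.05, abs=0.003)

    def test_null_family_wise_rate_close_to_alpha(self):
        # modest Monte-Carlo check; the full calibration runs elsewhere
        rng = np.random.default_rng(7)
        c = dunnett_critical_value(15, [15, 15, 15], seed=0)
        reps = 3000
        ctl = rng.normal(size=(reps, 15))
        trt = [rng.normal(size=(reps, 15)) for _ in range(3)]
        tmax = np.abs(dunnett_tstats(ctl, trt)).max(axis=-1)
        rate = float((tmax > c).mean())
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 4 * se


class TestFisher:
    def test_balanced_table_p_is_one(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_diagonal_three_table(self):
        # margins 3/3: probabilities {1, 9, 9, 1}/20 -> two-sided 0.1
        assert fisher_exact([[3, 0], [0, 3]]).p_value == pytest.approx(
            0.1, abs=1e-12)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 10, size=4)
            if (a + b == 0 or c + d == 0):
                continue
            p = fisher_exact([[a, b], [c, d]]).p_value
            assert p == pytest.approx(fisher_oracle(a, b, c, d),
                                      abs=1e-10)

    def test_invariant_to_row_and_column_swap(self):
        table = [[7, 2], [3, 9]]
        p = fisher_exact(table).p_value
        assert fisher_exact([[3, 9], [7, 2]]).p_value == pytest.approx(p)
        assert fisher_exact([[2, 7], [9, 3]]).p_value == pytest.approx(p)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])


class TestChiSquare:
    def test_table_equal_to_expected_gives_zero(self):
        res = chi_square([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        a, b, c, d = 12, 5, 7, 15
        n = a + b + c + d
        expected = (a * d - b * c) ** 2 * n / (
            (a + b) * (c + d) * (a + c) * (b + d))
        res = chi_square([[a, b], [c, d]])
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.df == 1.0

    def test_null_rejection_rate_close_to_alpha(self):
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.multinomial(80, [0.25] * 4).reshape(2, 2)
            if (x.sum(0) == 0).any() or (x.sum(1) == 0).any():
                continue
            rejections += chi_square(x).p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 4 * se

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square([[0, 0], [3, 4]])


class TestRanks:
    def test_simple_ordering(self):
        assert list(rank_transform([10.0, 20.0, 30.0])) == [1.0, 2.0, 3.0]

    def test_ties_mid_ranked(self):
        assert list(rank_transform([5.0, 5.0, 9.0])) == [1.5, 1.5, 3.0]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        assert np.array_equal(rank_transform(x),
                              rank_transform(np.exp(x)))


class TestRequiredN:
    def test_unit_effect_matches_brute_force_power_curve(self):
        # independent oracle: statsmodels' power solver
        from statsmodels.stats.power import TTestIndPower

        n_cont = TTestIndPower().solve_power(effect_size=1.0, alpha=0.05,
                                             power=0.8)
        assert required_n(1.0) == int(np.ceil(n_cont))

    @pytest.mark.parametrize("d", [0.5, 0.8, 1.2])
    def test_minimality(self, d):
        from neurophenopipe.stats import _t_power

        n = required_n(d)
        assert _t_power(n, d, 0.05, True) >= 0.8
        assert _t_power(n - 1, d, 0.05, True) < 0.8

    def test_huge_effect_needs_two_per_group(self):
        assert required_n(50.0) == 2

    def test_nonpositive_effect_rejected(self):
        with pytest.raises(ValueError):
            required_n(0.0)
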