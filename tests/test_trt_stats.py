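"""T-RT%, ICC, Bland-Altman, Wilcoxon, and rank statistics with oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tautrt.trt_stats import (
    bland_altman,
    group_difference,
    icc_band,
    icc_two_way,
    paired_wilcoxon,
    rank_association,
    trt_percent,
)


class TestTrtPercent:
    @pytest.mark.parametrize(
        "test,retest,expected",
        [(1.0, 1.0, 0.0), (1.1, 0.9, 20.0), (2.0, 1.0, 200.0 / 3.0)],
    )
    def test_printed_formula(self, test, retest, expected):
        assert trt_percent(test, retest) == pytest.approx(expected)

    def test_nonpositive_sum_rejected(self):
        with pytest.raises(ValueError):
            trt_percent(1.0, -1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(1e-3, 1e3),
        st.floats(1e-3, 1e3),
        st.floats(1e-3, 1e3),
    )
    def test_symmetric_scale_invariant_bounded(self, a, b, c):
        v = trt_percent(a, b)
        assert v == pytest.approx(trt_percent(b, a))
        assert v == pytest.approx(trt_percent(c * a, c * b), rel=1e-9)
        assert 0.0 <= v < 200.0

    def test_mean_matches_closed_form_at_5pct_cv(self, rng):
        # for Gaussian session pairs with within-subject CV c the expected
        # T-RT%% is (200 sqrt(2)/sqrt(pi)) c ~ 112.8 c
        c, mu, n = 0.05, 1.0, 10_000
        t = mu * (1 + c * rng.standard_normal(n))
        r = mu * (1 + c * rng.standard_normal(n))
        m = float(np.mean(trt_percent(t, r)))
        assert 5.0 <= m <= 6.3


class TestIcc:
    def test_identical_columns_give_unity(self):
        res = icc_two_way([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.icc == 1.0
        assert res.band == "excellent"

    def test_three_pair_matrix_matches_anova_oracle(self):
        # brute-force variance-component computation written out by hand
        data = np.array([[1.0, 1.1], [2.0, 2.1], [3.0, 3.05]])
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((data - grand) ** 2).sum()
            - k * ((data.mean(axis=1) - grand) ** 2).sum()
            - n * ((data.mean(axis=0) - grand) ** 2).sum()
        ) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        res = icc_two_way(data[:, 0], data[:, 1])
        assert res.icc == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin_absolute_and_consistency(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        t = rng.normal(1.0, 0.3, size=8)
        r = t + rng.normal(0.02, 0.08, size=8)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 2),
                "session": np.tile(["test", "retest"], 8),
                "value": np.column_stack([t, r]).ravel(),
            }
        )
        table = pingouin.intraclass_corr(df, targets="subject", raters="session",
                                         ratings="value").set_index("Type")
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        for form, key in (("absolute", "ICC(A,1)"), ("consistency", "ICC(C,1)")):
            if key not in table.index:
                key = {"ICC(A,1)": "ICC2", "ICC(C,1)": "ICC3"}[key]
            res = icc_two_way(t, r, form=form)
            assert res.icc == pytest.approx(table.loc[key, "ICC"], abs=1e-9)
            lo, hi = table.loc[key, ci_col]  # pingouin rounds to 2 decimals
            assert res.ci_low == pytest.approx(lo, abs=0.006)
            assert res.ci_high == pytest.approx(hi, abs=0.006)

    def test_simulation_recovers_variance_ratio(self, rng):
        # small version of the recovery experiment (full size in acceptance)
        sb, sw, n, reps = 0.15, 0.05, 7, 300
        expected = sb**2 / (sb**2 + sw**2)
        iccs = []
        for _ in range(reps):
            subj = rng.normal(1.0, sb, size=n)
            t = subj + rng.normal(0, sw, size=n)
            r = subj + rng.normal(0, sw, size=n)
            iccs.append(icc_two_way(t, r).icc)
        assert np.mean(iccs) == pytest.approx(expected, abs=0.05)

    def test_affine_invariance(self, rng):
        t = rng.normal(1.0, 0.3, size=7)
        r = t + rng.normal(0, 0.1, size=7)
        base = icc_two_way(t, r).icc
        shifted = icc_two_way(5.0 + 2.0 * t, 5.0 + 2.0 * r).icc
        assert shifted == pytest.approx(base, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="3 complete pairs"):
            icc_two_way([1.0, 2.0], [1.0, 2.0])
        res = icc_two_way([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert not res.defined
        assert res.band == "undefined"


class TestIccBand:
    @pytest.mark.parametrize(
        "icc,band",
        [
            (0.97, "excellent"),  # highest reported reliability
            (0.62, "moderate"),  # lowest reported target-region reliability
            (0.49, "poor"),
            (0.5, "moderate"),  # boundary assigned upward
            (0.75, "good"),
            (0.9, "excellent"),
            (float("nan"), "undefined"),
        ],
    )
    def test_bands(self, icc, band):
        assert icc_band(icc) == band

    def test_icc_above_one_rejected(self):
        with pytest.raises(ValueError):
            icc_band(1.2)


class TestBlandAltman:
    def test_identical_pairs(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.bias == 0.0
        assert ba.loa_high - ba.loa_low == 0.0

    def test_symmetric_two_pair_case(self):
        ba = bland_altman([1.1, 0.9], [1.0, 1.0])
        assert ba.bias == pytest.approx(0.0)
        sd = np.std([0.1, -0.1], ddof=1)
        assert ba.loa_high == pytest.approx(1.96 * sd)

    def test_loa_width_matches_difference_sd(self, rng):
        sigma = 0.07
        t = rng.normal(1.0, 0.2, size=1000)
        r = t - rng.normal(0.0, sigma, size=1000)
        ba = bland_altman(t, r)
        half_width = (ba.loa_high - ba.loa_low) / 2
        assert half_width == pytest.approx(1.96 * sigma, rel=0.10)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestWilcoxon:
    def test_exact_p_matches_sign_enumeration(self, rng):
        d = rng.normal(0.05, 0.1, size=6)
        while len(np.unique(np.abs(d))) < 6 or np.any(d == 0):
            d = rng.normal(0.05, 0.1, size=6)
        t = 1.0 + d
        r = np.ones(6)
        res = paired_wilcoxon(t, r, alternative="greater")
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = ranks[d > 0].sum()
        count = sum(
            sum(rk for rk, s in zip(ranks, signs) if s) >= w_obs
            for signs in itertools.product([False, True], repeat=6)
        )
        assert res.p_value == pytest.approx(count / 64.0, abs=1e-12)

    def test_extreme_ranking_smallest_one_sided_p(self):
        t = np.array([1.1, 1.2, 1.3, 1.4, 1.5, 1.6])
        r = np.ones(6)
        res = paired_wilcoxon(t, r, alternative="greater")
        assert res.p_value == pytest.approx(1.0 / 64.0)

    def test_antisymmetric_differences_near_null(self):
        d = np.array([-0.3, 0.3, -0.2, 0.2, -0.1, 0.1])
        res = paired_wilcoxon(1.0 + d, np.ones(6))
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_flagged(self):
        res = paired_wilcoxon([1.0, 2.0], [1.0, 2.0])
        assert res.degenerate
        assert np.isnan(res.p_value)


class TestRankStatistics:
    def test_monotone_pairs(self):
        rho, _ = rank_association([1, 2, 3, 4], [10, 20, 25, 90])
        assert rho == 1.0
        rho, _ = rank_association([1, 2, 3], [3, 2, 1])
        assert rho == -1.0

    def test_matches_direct_rank_formula(self, rng):
        x = rng.permutation(10).astype(float)
        y = rng.permutation(10).astype(float)
        rho, _ = rank_association(x, y)
        rx = np.argsort(np.argsort(x)) + 1
        ry = np.argsort(np.argsort(y)) + 1
        d2 = ((rx - ry) ** 2).sum()
        expected = 1 - 6 * d2 / (10 * (100 - 1))
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_input_flagged(self):
        rho, p = rank_association([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho)

    def test_kruskal_wallis_separates_groups(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20)
        stat, p = group_difference(a, b)
        assert p < 1e-6
        with pytest.raises(ValueError):
            group_difference(a)
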