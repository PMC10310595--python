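"""Censored summary statistics and group comparisons.

The product-limit oracle here is computed by hand from first principles
(survival steps on flipped data) independently of the implementation.
"""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines.statistics import logrank_test

import soilrisk as sr


def km_mean_oracle(values, censored):
    """Brute-force product-limit mean on flipped left-censored data."""
    M = max(values) + 1.0
    items = sorted(zip([M - v for v in values], [not c for c in censored]))
    n_risk = len(items)
    s = 1.0
    area = 0.0
    prev_t = 0.0
    i = 0
    while i < len(items):
        t = items[i][0]
        area += s * (t - prev_t)
        d = r = 0
        while i < len(items) and items[i][0] == t:
            r += 1
            d += items[i][1]
            i += 1
        if d:
            s *= 1.0 - d / n_risk
        n_risk -= r
        prev_t = t
    return M - area


class TestKmSummary:
    def test_hand_computed_product_limit(self):
        # {<1, 2, 3}: survival steps 2/3 then 1/3 on the flipped scale,
        # restricted-mean area 2, mean = 4 - 2 = 2.0
        s = sr.km_summary([1.0, 2.0, 3.0], [True, False, False], flip_constant=4.0)
        assert s.mean == pytest.approx(2.0, abs=1e-12)
        assert s.pct_censored == pytest.approx(100.0 / 3.0)
        assert "censored_min" in s.flags

    def test_uncensored_equals_arithmetic(self):
        vals = np.random.default_rng(1).lognormal(2.0, 1.0, 37)
        s = sr.km_summary(vals)
        assert s.mean == pytest.approx(np.mean(vals), abs=1e-12)
        assert s.sd == pytest.approx(np.std(vals, ddof=1), abs=1e-12)
        assert s.median == pytest.approx(np.quantile(vals, 0.5, method="inverted_cdf"), abs=1e-12)
        assert s.p95 == pytest.approx(np.quantile(vals, 0.95, method="inverted_cdf"), abs=1e-12)
        assert s.maximum == vals.max()
        assert s.pct_censored == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle_under_censoring(self, seed):
        g = np.random.default_rng(seed)
        vals = g.lognormal(0.5, 1.0, 30)
        lod = np.quantile(vals, g.uniform(0.1, 0.5))
        cens = vals < lod
        nums = np.where(cens, lod, vals)
        s = sr.km_summary(nums, cens)
        assert s.mean == pytest.approx(km_mean_oracle(nums, cens), rel=1e-10)

    @given(st.integers(0, 10_000), st.floats(1.0, 100.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_flip_invariance_and_substitution_bounds(self, seed, extra):
        g = np.random.default_rng(seed)
        vals = g.lognormal(0.0, 1.0, 20)
        lod = float(np.quantile(vals, 0.4))
        cens = vals < lod
        if cens.all() or not cens.any():
            return
        nums = np.where(cens, lod, vals)
        base = sr.km_summary(nums, cens)
        moved = sr.km_summary(nums, cens, flip_constant=nums.max() + extra)
        assert moved.mean == pytest.approx(base.mean, rel=1e-10)
        assert moved.median == pytest.approx(base.median, rel=1e-9)
        lo = np.where(cens, 0.0, nums).mean()
        hi = nums.mean()
        assert lo - 1e-9 <= base.mean <= hi + 1e-9

    def test_all_censored_is_degenerate_upper_bound(self):
        s = sr.km_summary([4.0, 4.0, 6.0], [True, True, True])
        assert "all_censored" in s.flags and "upper_bound" in s.flags
        assert s.mean == 4.0 and s.median == 4.0

    def test_measurement_objects_accepted(self):
        meas = [sr.Measurement(None, censored=True, detection_limit=1.0),
                sr.Measurement(2.0), sr.Measurement(3.0)]
        assert sr.km_summary(meas).mean == pytest.approx(2.0)


class TestPetoPeto:
    def test_identical_groups_give_p_one(self):
        r = sr.peto_peto([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        r = sr.peto_peto([1.0, 2.0, 3.0], [100.0, 200.0, 300.0])
        assert r.p_value < 0.05

    def test_exhaustive_permutation_three_vs_three(self):
        # complete separation: 2 of the 20 assignments are as extreme
        r = sr.peto_peto([1.0, 2.0, 3.0], [100.0, 200.0, 300.0], method="permutation")
        assert "exhaustive_permutation" in r.flags
        assert r.p_value == pytest.approx(2.0 / 20.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_statistic_matches_lifelines(self, seed):
        g = np.random.default_rng(seed)
        a = g.lognormal(0.0, 0.7, 20)
        b = g.lognormal(0.4, 0.7, 25)
        lod = 0.8
        am, bm = a < lod, b < lod
        a, b = np.where(am, lod, a), np.where(bm, lod, b)
        r = sr.peto_peto(a, b, am, bm)
        M = max(a.max(), b.max()) + 1.0
        ll = logrank_test(M - a, M - b, event_observed_A=~am, event_observed_B=~bm,
                          weightings="peto")
        assert r.statistic == pytest.approx(ll.test_statistic, rel=1e-10)
        assert r.p_value == pytest.approx(ll.p_value, rel=1e-10)

    def test_degenerate_group_skipped(self):
        r = sr.peto_peto([4.0, 4.0], [1.0, 2.0, 3.0], [True, True], [False] * 3)
        assert "skipped_degenerate_group" in r.flags
        assert math.isnan(r.p_value)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            sr.peto_peto([1.0], [1.0, 2.0])


class TestPairwiseScreen:
    def test_identical_distribution_flagged(self, small_dataset):
        # Fe has no anthropogenic burning loading in the default generator
        # and its dismantling factor decays over the groups kept here
        samples = [s for s in small_dataset.samples
                   if s.site_group in (sr.SiteGroup.COMMUNITY, sr.SiteGroup.BACKGROUND)]
        res = sr.pairwise_screen(samples, ["Fe"])
        assert "Fe" in res.no_difference

    def test_shifted_element_detected(self, small_dataset):
        res = sr.pairwise_screen(small_dataset.samples, ["Pb", "Cu"])
        assert "Pb" not in res.no_difference
        assert "Cu" not in res.no_difference
        pb_burn = [r for r in res.results if r.element == "Pb"
                   and "burning" in (r.group_a, r.group_b)]
        assert pb_burn and all(r.p_adjusted < 0.05 for r in pb_burn)

    def test_adjusted_p_not_below_raw(self, small_dataset):
        res = sr.pairwise_screen(small_dataset.samples, ["Pb", "Zn", "Cr"])
        for r in res.results:
            if r.p_adjusted is not None:
                assert r.p_adjusted >= r.p_value - 1e-12

    def test_single_group_rejected(self, small_dataset):
        only = [s for s in small_dataset.samples if s.site_group == sr.SiteGroup.BURNING]
        with pytest.raises(ValueError, match="2 site groups"):
            sr.pairwise_screen(only, ["Pb"])

    def test_absent_element_skipped(self, small_dataset):
        res = sr.pairwise_screen(small_dataset.samples, ["Pb", "Xx"])
        assert res.skipped == ["Xx"]


class TestQa:
    def test_identity_and_exact_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        fit = sr.comparability_regression(x, x)
        assert fit["slope"] == pytest.approx(1.0) and fit["intercept"] == pytest.approx(0.0)
        assert fit["r2"] == pytest.approx(1.0)
        fit2 = sr.comparability_regression(x, [2 * v + 1 for v in x])
        assert fit2["slope"] == pytest.approx(2.0) and fit2["intercept"] == pytest.approx(1.0)

    def test_against_normal_equations(self):
        g = np.random.default_rng(3)
        x = g.uniform(1, 100, 13)
        y = 1.07 * x - 3.0 + g.normal(0, 5, 13)
        fit = sr.comparability_regression(x, y)
        xc = x - x.mean()
        slope = float(np.sum(xc * y) / np.sum(xc * xc))
        intercept = float(y.mean() - slope * x.mean())
        assert fit["slope"] == pytest.approx(slope, abs=1e-10)
        assert fit["intercept"] == pytest.approx(intercept, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sr.comparability_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("measured,certified,expected",
                             [(100.0, 100.0, 100.0), (0.0, 50.0, 0.0), (95.0, 100.0, 95.0)])
    def test_srm_recovery(self, measured, certified, expected):
        assert sr.srm_recovery(measured, certified) == pytest.approx(expected)

    def test_srm_recovery_bad_certified(self):
        with pytest.raises(ValueError):
            sr.srm_recovery(1.0, 0.0)
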