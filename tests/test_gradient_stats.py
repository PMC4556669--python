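import itertools

import numpy as np
import pytest
from scipy import stats

from kaedeflux import (
    BinnedProfile,
    GradientPoint,
    anova_tukey,
    fit_gradient_rate,
    fit_spatial_gradient,
    mann_whitney_exact,
    region_summary,
)


def make_binned(means, timepoint_index=0):
    means = np.asarray(means, dtype=float)
    n = len(means)
    return BinnedProfile(
        bin_means=means,
        bin_ranges=[(i * 10 + 1, (i + 1) * 10) for i in range(n)],
        valid_counts=np.where(np.isfinite(means), 10, 0),
        timepoint_index=timepoint_index,
    )


def brute_force_two_sided_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating every rank assignment."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(b) / 2.0
    us = []
    for combo in itertools.combinations(range(1, len(pooled) + 1), n1):
        us.append(sum(combo) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    return float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-9))


class TestSpatialGradient:
    def test_flat_profile_zero_slope(self):
        g = fit_spatial_gradient(make_binned(np.full(15, 1.3)))
        assert g.slope == 0.0 and g.r_squared == 0.0 and g.n_bins_used == 15

    def test_exact_linear_input(self):
        centers = np.arange(15) * 10 + 5.5
        g = fit_spatial_gradient(make_binned(2.0 - 0.01 * centers))
        assert g.slope == pytest.approx(-0.01, abs=1e-12)
        assert g.intercept == pytest.approx(2.0, abs=1e-10)
        assert g.r_squared == pytest.approx(1.0)

    def test_matches_polyfit_oracle(self, rng):
        means = rng.uniform(0, 2, 15)
        g = fit_spatial_gradient(make_binned(means))
        slope_ref, intercept_ref = np.polyfit(np.arange(15) * 10 + 5.5, means, 1)
        assert g.slope == pytest.approx(slope_ref, abs=1e-10)
        assert g.intercept == pytest.approx(intercept_ref, abs=1e-10)

    def test_missing_bins_dropped_pairwise(self, rng):
        means = rng.uniform(0, 2, 15)
        means[[2, 7, 11]] = np.nan
        g = fit_spatial_gradient(make_binned(means))
        ok = np.isfinite(means)
        slope_ref = np.polyfit((np.arange(15) * 10 + 5.5)[ok], means[ok], 1)[0]
        assert g.n_bins_used == 12 and g.slope == pytest.approx(slope_ref, abs=1e-10)

    def test_too_few_bins_rejected(self):
        means = np.full(15, np.nan)
        means[:2] = 1.0
        with pytest.raises(ValueError, match="3"):
            fit_spatial_gradient(make_binned(means))

    def test_shift_invariance_and_scale_linearity(self, rng):
        means = rng.uniform(0, 2, 15)
        base = fit_spatial_gradient(make_binned(means)).slope
        shifted = fit_spatial_gradient(make_binned(means + 5.0)).slope
        scaled = fit_spatial_gradient(make_binned(3.0 * means)).slope
        assert shifted == pytest.approx(base, abs=1e-12)
        assert scaled == pytest.approx(3.0 * base, abs=1e-12)

    def test_um_axis_rescales_slope(self):
        centers = np.arange(15) * 10 + 5.5
        binned = make_binned(2.0 - 0.01 * centers)
        g_um = fit_spatial_gradient(binned, position_unit="um", pixel_size_um=0.2)
        assert g_um.slope == pytest.approx(-0.01 / 0.2, abs=1e-10)


class TestGradientRate:
    def _series(self, slopes, times=None):
        times = times if times is not None else np.arange(len(slopes)) * 10.0
        return [
            GradientPoint(timepoint_min=t, slope=s, intercept=0.0, r_squared=1.0,
                          n_bins_used=15)
            for t, s in zip(times, slopes)
        ]

    def test_constant_gradients_zero_rate(self):
        r = fit_gradient_rate(self._series(np.full(10, -0.02)))
        assert r.rate == 0.0 and r.n_timepoints_used == 10

    def test_exact_linear_input(self):
        t = np.arange(10) * 10.0
        r = fit_gradient_rate(self._series(-0.001 * t, t))
        assert r.rate == pytest.approx(-0.001, abs=1e-15)

    def test_matches_polyfit_oracle(self, rng):
        slopes = rng.normal(-0.01, 0.002, 10)
        r = fit_gradient_rate(self._series(slopes))
        assert r.rate == pytest.approx(
            np.polyfit(np.arange(10) * 10.0, slopes, 1)[0], abs=1e-10
        )

    def test_duplicate_timepoints_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            fit_gradient_rate(self._series([0.1, 0.2, 0.3], [0.0, 10.0, 10.0]))


class TestRegionSummary:
    def test_constant_profile(self):
        binned = [make_binned(np.full(15, 0.7), t) for t in range(10)]
        assert np.allclose(region_summary(binned, "growth_cone"), 0.7)
        assert np.allclose(region_summary(binned, "proximal"), 0.7)

    def test_linear_profile_region_values(self):
        centers = np.arange(15) * 10 + 5.5
        binned = [make_binned(2.0 - 0.01 * centers, 0)]
        assert region_summary(binned, "growth_cone")[0] == pytest.approx(1.945)
        assert region_summary(binned, "proximal")[0] == pytest.approx(0.545)


class TestAnovaTukey:
    def test_identical_groups(self):
        g = {"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}
        res = anova_tukey(g)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_one_separated_group_flagged(self):
        res = anova_tukey({"g1": [1, 2, 3], "g2": [1, 2, 3], "g3": [10, 11, 12]})
        flags = {pair: sig for pair, sig, _ in res.pairwise}
        assert flags[("g1", "g2")] is False
        assert flags[("g1", "g3")] is True and flags[("g2", "g3")] is True

    def test_planted_growth_cone_effect_detected(self, rng):
        # 4 groups mimicking the 90-min region comparison: +UTR growth cones high
        groups = {
            "+UTR gc": rng.normal(0.5, 0.05, 10),
            "+UTR prox": rng.normal(0.1, 0.05, 10),
            "-UTR gc": rng.normal(0.1, 0.05, 6),
            "-UTR prox": rng.normal(0.1, 0.05, 6),
        }
        res = anova_tukey(groups)
        flags = {frozenset(pair): sig for pair, sig, _ in res.pairwise}
        assert flags[frozenset(("+UTR gc", "-UTR gc"))] is True
        assert flags[frozenset(("-UTR gc", "-UTR prox"))] is False

    def test_tukey_flags_subset_of_unadjusted_t(self, rng):
        samples = {f"g{i}": rng.normal(i * 0.4, 1.0, 8) for i in range(4)}
        res = anova_tukey(samples, alpha=0.05)
        for (l1, l2), sig, _ in res.pairwise:
            t_p = stats.ttest_ind(samples[l1], samples[l2]).pvalue
            if sig:
                assert t_p < 0.05  # adjustment can only remove flags

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            anova_tukey({"a": [1.0], "b": [1, 2], "c": [1, 2]})


class TestMannWhitney:
    def test_single_observations(self):
        res = mann_whitney_exact([0.0], [1.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_three_vs_three_separated(self):
        res = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(0.1)

    def test_exhaustive_agreement_with_enumeration_small_n(self, rng):
        # every split with combined n <= 10, exhaustive over all rank subsets
        for n in range(2, 11):
            for n1 in range(1, n):
                for subset in itertools.combinations(range(1, n + 1), n1):
                    a = np.array(subset, dtype=float)
                    b = np.array(sorted(set(range(1, n + 1)) - set(subset)), float)
                    res = mann_whitney_exact(a, b)
                    assert res.p_value == pytest.approx(
                        brute_force_two_sided_p(a, b), abs=1e-12
                    ), (a, b)

    @pytest.mark.parametrize("n1,n2", [(5, 6), (6, 6), (4, 8), (6, 10)])
    def test_random_samples_match_enumeration(self, n1, n2, rng):
        for _ in range(5):
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.5, 1, n2)
            res = mann_whitney_exact(a, b)
            assert res.p_value == pytest.approx(brute_force_two_sided_p(a, b), abs=1e-12)

    def test_ties_fall_back_to_corrected_normal(self):
        a = [1.0, 2.0, 2.0, 3.0]
        b = [2.0, 4.0, 5.0, 6.0]
        res = mann_whitney_exact(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue)
        assert "normal" in res.test_name

    def test_large_samples_use_approximation(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        res = mann_whitney_exact(a, b)
        assert 0.0 <= res.p_value <= 1.0 and "normal" in res.test_name

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney_exact([], [1.0])
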