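"""Trajectory ANOVA, Tukey post hoc, band-wise and event-timing tests."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eptools.thermal import (
    bandwise_kw,
    event_timing_kw,
    kruskal_two_sample,
    pointwise_posthoc,
    trajectory_anova,
    tukey_two_group,
)


def flat_grid(n_embryos, n_grid, level, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    return level + noise * rng.standard_normal((n_embryos, n_grid))


class TestTrajectoryAnova:
    def test_identical_cohorts_give_zero_F_unit_p(self):
        g = flat_grid(5, 100, 10.0, noise=1.0)
        res = trajectory_anova(g, g.copy())
        assert res.F == 0.0 and res.p == 1.0

    def test_default_grid_reports_df_1_99(self):
        a = flat_grid(4, 100, 10.0, noise=0.5, seed=1)
        b = flat_grid(4, 100, 12.0, noise=0.5, seed=2)
        res = trajectory_anova(a, b)
        assert (res.df_num, res.df_den) == (1, 99)

    def test_missing_grid_points_reduce_df_pairwise(self):
        a = flat_grid(4, 100, 10.0, noise=0.5, seed=1)
        b = flat_grid(4, 100, 12.0, noise=0.5, seed=2)
        a[:, :5] = np.nan
        res = trajectory_anova(a, b)
        assert (res.df_num, res.df_den) == (1, 94)

    def test_equals_paired_t_squared(self):
        rng = np.random.default_rng(3)
        a = rng.normal(10, 1, (6, 40))
        b = rng.normal(11, 1, (6, 40))
        res = trajectory_anova(a, b)
        t, p = stats.ttest_rel(np.mean(a, axis=0), np.mean(b, axis=0))
        assert res.F == pytest.approx(t**2, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            trajectory_anova(flat_grid(1, 10, 1.0), flat_grid(3, 10, 1.0))


class TestPointwisePosthoc:
    def test_identical_cohorts_have_empty_significant_region(self):
        g = flat_grid(6, 50, 10.0, noise=1.0, seed=4)
        _, regions, significant = pointwise_posthoc(g, g.copy())
        assert regions == [] and significant == frozenset()

    def test_two_group_tukey_equals_pooled_t_test(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 11)
        _, p_tukey = tukey_two_group(x, y)
        _, p_t = stats.ttest_ind(x, y, equal_var=True)
        assert p_tukey == pytest.approx(p_t, rel=1e-6)

    def test_injected_region_detected_at_right_location(self):
        rng = np.random.default_rng(6)
        n_grid = 100
        a = 10 + 0.5 * rng.standard_normal((12, n_grid))
        b = 10 + 0.5 * rng.standard_normal((12, n_grid))
        rel = np.linspace(0, 1, n_grid)
        b[:, (rel >= 0.3) & (rel <= 0.6)] += 5.0
        _, regions, _ = pointwise_posthoc(a, b)
        widest = max(regions, key=lambda r: r.end_index - r.start_index)
        assert 0.3 <= widest.midpoint <= 0.6
        assert widest.direction == "increased"

    def test_region_detection_invariant_to_constant_shift(self):
        rng = np.random.default_rng(7)
        a = rng.normal(10, 1, (8, 60))
        b = rng.normal(12, 1, (8, 60))
        _, _, sig = pointwise_posthoc(a, b)
        _, _, sig_shifted = pointwise_posthoc(a + 100.0, b + 100.0)
        assert sig == sig_shifted

    def test_underpopulated_grid_points_skipped(self):
        a = flat_grid(4, 10, 10.0, noise=1.0, seed=8)
        b = flat_grid(4, 10, 10.0, noise=1.0, seed=9)
        a[1:, 3] = np.nan  # one embryo left at this point
        pvals, _, _ = pointwise_posthoc(a, b)
        assert np.isnan(pvals[3]) and np.isfinite(np.delete(pvals, 3)).all()


class TestBandwiseKW:
    def test_bonferroni_threshold_is_alpha_over_sixty(self):
        a = np.abs(np.random.default_rng(0).normal(1, 0.1, (3, 60)))
        res = bandwise_kw(a, a + 0.0)
        assert res.corrected_alpha == pytest.approx(0.05 / 60)
        assert float(f"{res.corrected_alpha:.2g}") == 0.00083

    def test_identical_groups_give_no_significant_bands(self):
        a = np.abs(np.random.default_rng(1).normal(1, 0.1, (5, 60)))
        res = bandwise_kw(a, a.copy())
        assert np.all(res.H == 0.0) and np.all(res.p == 1.0)
        assert res.significant_bands == frozenset()

    def test_band_specific_effect_recovered_with_direction(self):
        rng = np.random.default_rng(12)
        a = np.abs(rng.normal(1, 0.05, (20, 60)))
        b = np.abs(rng.normal(1, 0.05, (20, 60)))
        b[:, 20] *= 4.0
        res = bandwise_kw(a, b)
        assert res.significant_bands == frozenset({20})
        assert res.directions[20] == "increased"
        assert res.hz_ranges == ((2.0, 2.1),)

    def test_no_band_at_or_above_bonferroni_reported(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            rng2 = np.random.default_rng(seed)
            a = np.abs(rng2.normal(1, 0.3, (6, 60)))
            b = np.abs(rng2.normal(1, 0.3, (6, 60)))
            res = bandwise_kw(a, b)
            assert all(res.p[k] < 0.05 / 60 for k in res.significant_bands)

    def test_two_group_kw_matches_rank_sum_on_tie_free_data(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 9), rng.normal(0.5, 1, 7)
        _, p_kw = kruskal_two_sample(x, y)
        p_mw = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                  use_continuity=False).pvalue
        assert p_kw == pytest.approx(p_mw, rel=1e-9)

    def test_degenerate_all_identical_band(self):
        a = np.ones((4, 60))
        res = bandwise_kw(a, np.ones((4, 60)))
        assert res.H[0] == 0.0 and res.p[0] == 1.0


class TestEventTimingKW:
    def test_identical_samples_unchanged(self):
        t = pd.DataFrame({"rotation": [10.0, 10.0, 10.0]})
        res = event_timing_kw(t, t.copy())
        assert res.tests["rotation"].p == 1.0
        assert res.tests["rotation"].direction == "unchanged"

    def test_accelerated_cohort_detected(self):
        rng = np.random.default_rng(5)
        cool = pd.DataFrame({e: 100 + rng.normal(0, 2, 20) for e in
                             ("rotation", "heart", "crawling", "radula")})
        warm = cool * 0.8
        res = event_timing_kw(cool, warm)
        for event, test in res.tests.items():
            assert test.direction == "accelerated"
            assert test.p < 0.001

    def test_single_embryo_group_skipped(self):
        a = pd.DataFrame({"rotation": [10.0, 11.0], "heart": [20.0, np.nan]})
        b = pd.DataFrame({"rotation": [9.0, 10.0], "heart": [18.0, 19.0]})
        res = event_timing_kw(a, b)
        assert "heart" in res.skipped and "rotation" in res.tests
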