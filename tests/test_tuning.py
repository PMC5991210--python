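"""Tuning statistics: t-tests, ANOVAs, curve summaries, FRA/BF, tonotopy."""

import numpy as np
import pytest
from scipy import stats

from ildpipe.tuning import (
    GradientFit,
    best_frequency,
    bf_variation,
    build_fra,
    group_average_curves,
    ild_curve_summary,
    paired_onetailed_p,
    smooth_fra,
    tonotopic_gradient,
    twoway_anova_balanced,
)
from ildpipe.tuning import test_frequency_sensitivity as freq_level_anova
from ildpipe.tuning import test_ild_sensitivity as ild_anova

ILDS = np.array([-30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0])


class TestPairedTTest:
    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        pre = rng.normal(size=(50, 12))
        post = rng.normal(size=(50, 12))
        mine = paired_onetailed_p(pre, post, axis=1)
        ref = stats.ttest_rel(post, pre, axis=1, alternative="greater").pvalue
        assert np.allclose(mine, ref)

    def test_zero_variance_identical_vectors_p_one(self):
        pre = np.ones(12)
        assert paired_onetailed_p(pre, pre) == 1.0

    def test_zero_variance_constant_positive_shift_p_zero(self):
        pre = np.ones(12)
        assert paired_onetailed_p(pre, pre + 3.0) == 0.0

    def test_large_effect_significant(self):
        rng = np.random.default_rng(1)
        pre = rng.normal(0, 0.01, 12)
        assert paired_onetailed_p(pre, pre + 10.0) < 1e-6

    def test_single_rep_rejected(self):
        with pytest.raises(ValueError):
            paired_onetailed_p(np.ones(1), np.ones(1))


class TestIldAnova:
    def test_strong_group_shift_flagged(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, (5, 12)) for _ in range(7)]
        groups[3] = groups[3] + 10.0
        flags, p = ild_anova(groups)
        assert flags.all() and (p < 1e-6).all()

    def test_constant_data_not_flagged(self):
        groups = [np.ones((2, 12)) for _ in range(7)]
        flags, p = ild_anova(groups)
        assert not flags.any()
        assert np.isnan(p).all()

    def test_matches_scipy_scalar(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=(1, 12)) for _ in range(7)]
        _, p = ild_anova(groups)
        ref = stats.f_oneway(*[g[0] for g in groups]).pvalue
        assert p[0] == pytest.approx(ref)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            ild_anova([np.ones((1, 1))] * 7)


class TestIldCurveSummary:
    def test_flat_curve_symmetric_centroid_and_tie_rule(self):
        s = ild_curve_summary(np.ones(7), ILDS)
        assert s.weighted_ild_db == pytest.approx(0.0)
        assert s.peak_ild_db == -30.0  # tie -> most contralateral

    def test_single_sided_response(self):
        s = ild_curve_summary(np.array([1, 0, 0, 0, 0, 0, 0.0]), ILDS)
        assert s.weighted_ild_db == pytest.approx(-30.0)
        assert s.peak_ild_db == -30.0

    def test_hand_arithmetic_example(self):
        s = ild_curve_summary(np.array([2, 1, 1, 1, 1, 1, 1.0]), ILDS)
        assert s.weighted_ild_db == pytest.approx(-30.0 / 8.0)
        assert s.steepest_midpoint_db == pytest.approx(-25.0)
        assert np.max(np.abs(s.slopes)) == pytest.approx(1.0)
        assert len(s.slopes) == 6

    def test_nonpositive_mass_flagged_undefined(self):
        s = ild_curve_summary(np.full(7, -1.0), ILDS)
        assert not s.weighted_defined and np.isnan(s.weighted_ild_db)

    def test_negative_flooring_keeps_centroid_in_range(self):
        r = np.array([-5.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0])
        s = ild_curve_summary(r, ILDS)
        assert -30.0 <= s.weighted_ild_db <= 30.0

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_adding_constant_shrinks_centroid_toward_zero(self, c):
        r = np.array([3.0, 2.0, 1.5, 1.0, 0.5, 0.2, 0.1])
        base = ild_curve_summary(r, ILDS).weighted_ild_db
        shifted = ild_curve_summary(r + c, ILDS).weighted_ild_db
        oracle = float(ILDS @ (r + c) / (r + c).sum())
        assert shifted == pytest.approx(oracle)
        assert abs(shifted) < abs(base)


class TestGroupAverageCurves:
    def test_single_neuron_group_is_own_normalized_curve(self):
        curves = np.array([[1.0, 2.0, 4.0, 3.0, 2.0, 1.0, 0.5]])
        out = group_average_curves(curves, np.array([-10.0]), ILDS)
        assert np.allclose(out[-10.0], curves[0] / 4.0)
        assert out[-10.0].max() == pytest.approx(1.0)

    def test_identical_neurons_average_unchanged(self):
        c = np.array([0.1, 0.2, 0.4, 1.0, 0.4, 0.2, 0.1])
        out = group_average_curves(np.vstack([c, c]), np.array([0.0, 0.0]), ILDS)
        assert np.allclose(out[0.0], c)

    def test_mirrored_monotone_groups_are_symmetric(self):
        rng = np.random.default_rng(4)
        base = np.sort(rng.uniform(0.1, 1.0, (20, 7)), axis=1)
        contra = base[:, ::-1]   # peak at -30
        ipsi = base               # peak at +30
        curves = np.vstack([contra, ipsi])
        peaks = np.array([-30.0] * 20 + [30.0] * 20)
        out = group_average_curves(curves, peaks, ILDS)
        assert np.allclose(out[-30.0], out[30.0][::-1])

    def test_empty_groups_omitted(self):
        out = group_average_curves(np.ones((1, 7)), np.array([0.0]), ILDS)
        assert set(out) == {0.0}


class TestFra:
    def test_flat_grid_smoothing_identity(self):
        fra = np.ones((18, 4))
        assert np.allclose(smooth_fra(fra), fra)

    def test_interior_impulse_spreads_to_thirds(self):
        x = np.zeros(9)
        x[4] = 1.0
        sm = smooth_fra(x)
        assert np.allclose(sm[3:6], 1.0 / 3.0)

    def test_edge_impulse_renormalized_to_half(self):
        x = np.zeros(9)
        x[0] = 1.0
        sm = smooth_fra(x)
        assert sm[0] == pytest.approx(0.5)
        assert sm[1] == pytest.approx(1.0 / 3.0)

    def test_build_fra_means_and_missing_cell_error(self):
        freqs = np.array([1.0, 2.0])
        levels = np.array([10.0, 20.0])
        fl = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 1.0, 2.0])
        lv = np.array([10.0, 10.0, 20.0, 10.0, 20.0, 20.0, 20.0, 10.0])
        resp = np.arange(8.0)
        fra, _ = build_fra(resp, fl, lv, freqs, levels)
        assert fra[0, 0] == pytest.approx(np.mean([0.0, 1.0]))
        with pytest.raises(ValueError):
            build_fra(resp[:3], fl[:3], lv[:3], freqs, levels)


class TestTwoWayAnova:
    def test_matches_statsmodels_type2_on_balanced_grid(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        import pandas as pd
        rng = np.random.default_rng(5)
        a, b, r = 6, 4, 5
        cells = rng.normal(size=(a, b, r)) + rng.normal(size=(a, 1, 1))
        mine = twoway_anova_balanced(cells)
        df = pd.DataFrame({
            "y": cells.ravel(),
            "f": np.repeat(np.arange(a), b * r),
            "l": np.tile(np.repeat(np.arange(b), r), a),
        })
        fit = smf.ols("y ~ C(f) + C(l) + C(f):C(l)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert float(mine["p_freq"]) == pytest.approx(tab.loc["C(f)", "PR(>F)"])
        assert float(mine["p_level"]) == pytest.approx(tab.loc["C(l)", "PR(>F)"])

    def test_level_only_effect_sets_level_flag(self):
        rng = np.random.default_rng(7)
        n = 72
        freqs = np.repeat(np.arange(18.0), 4 * 2)
        levels = np.tile(np.repeat(np.arange(4.0), 2), 18)
        resp = levels * 5.0 + rng.normal(0, 0.5, freqs.size)
        res = freq_level_anova(resp, freqs, levels)
        assert res["level_sensitive"] and not res["freq_sensitive"]

    def test_planted_fra_sets_freq_flag(self):
        rng = np.random.default_rng(7)
        freqs = np.repeat(np.arange(18.0), 4 * 3)
        levels = np.tile(np.repeat(np.arange(4.0), 3), 18)
        resp = np.exp(-0.5 * ((freqs - 9) / 2.0) ** 2) + rng.normal(0, 0.1, freqs.size)
        res = freq_level_anova(resp, freqs, levels)
        assert res["freq_sensitive"]

    def test_unbalanced_grid_falls_back_to_type2(self):
        rng = np.random.default_rng(8)
        freqs = np.concatenate([np.repeat(np.arange(3.0), 8), [0.0]])
        levels = np.concatenate([np.tile(np.repeat(np.arange(2.0), 4), 3), [1.0]])
        resp = rng.normal(size=freqs.size)
        res = freq_level_anova(resp, freqs, levels)
        assert np.isfinite(res["p_freq"])


class TestBestFrequency:
    def test_impulse_fra_with_quiet_baseline(self):
        fra = np.zeros((18, 4))
        fra[10] = 1.0
        freqs = np.geomspace(1900, 50000, 18)
        bf, valid = best_frequency(fra, freqs, pre_peaks=np.full(100, 0.001))
        assert bf == pytest.approx(freqs[10])
        assert valid

    def test_flat_fra_tie_breaks_to_lowest_and_invalid(self):
        fra = np.ones((18, 4)) * 0.01
        freqs = np.geomspace(1900, 50000, 18)
        rng = np.random.default_rng(9)
        bf, valid = best_frequency(fra, freqs, pre_peaks=rng.normal(1.0, 0.5, 200))
        assert bf == pytest.approx(freqs[0])
        assert not valid

    def test_three_sd_rule_boundary(self):
        fra = np.zeros((5, 2))
        fra[2] = 1.0
        freqs = np.arange(5.0)
        pre = np.concatenate([np.full(50, 0.5), np.full(50, 0.7)])
        thr = pre.mean() + 3 * pre.std(ddof=1)
        _, valid = best_frequency(fra, freqs, pre)
        assert valid == (1.0 >= thr)


class TestTonotopicGradient:
    def _map(self, angle_deg, n=60, seed=0):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 500, size=(n, 2))
        th = np.deg2rad(angle_deg)
        proj = pos @ np.array([np.cos(th), np.sin(th)])
        bf = 2.0 ** (15 - 4 * (proj - proj.min()) / np.ptp(proj))
        return pos, bf

    def test_gradient_along_zero_axis(self):
        pos, bf = self._map(0.0)
        fit = tonotopic_gradient(pos, bf)
        assert fit.angle_deg == pytest.approx(0.0, abs=1.0)
        assert fit.correlation_at_angle == pytest.approx(-1.0, abs=1e-6)

    def test_rotation_equivariance(self):
        pos, bf = self._map(90.0)
        fit = tonotopic_gradient(pos, bf)
        assert fit.angle_deg == pytest.approx(90.0, abs=1.0)

    def test_profile_antisymmetry(self):
        pos, bf = self._map(37.0)
        fit = tonotopic_gradient(pos, bf)
        assert np.allclose(fit.profile[:180], -fit.profile[180:], atol=1e-12)

    def test_equal_bfs_undefined(self):
        pos = np.random.default_rng(1).uniform(0, 100, (10, 2))
        fit = tonotopic_gradient(pos, np.full(10, 8000.0))
        assert not fit.defined and np.isnan(fit.angle_deg)

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError):
            tonotopic_gradient(np.zeros((2, 2)), np.array([1000.0, 2000.0]))


class TestBfVariation:
    def test_equal_bfs_zero(self):
        assert bf_variation(np.full(5, 12000.0)) == 0.0

    def test_two_point_example(self):
        assert bf_variation(np.array([10000.0, 40000.0])) == pytest.approx(np.sqrt(2))

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        bfs = rng.uniform(2000, 40000, 20)
        assert bf_variation(2 * bfs) == pytest.approx(bf_variation(bfs))

    def test_single_bf_undefined(self):
        with pytest.raises(ValueError):
            bf_variation(np.array([1000.0]))
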