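"""Relative hazards, outlier flagging, averaging and slope diagnostics.

The packaged SEER 9 lung-cancer curves (three areas, both sexes) serve as
the reference dataset: their per-age hazard ratios, outlier flags and
averaged relative hazards are pinned against independently computed values.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from llapc import (
    HazardCurve,
    adjust_curve,
    averaged_relative_hazard,
    flag_outliers,
    ratio_series,
    weighted_slope,
)
from llapc.relhazard import RelativeHazardSeries


def curve(midpoints, h, se, category=0, anchors=(6, 8)):
    n = len(h)
    return HazardCurve(midpoints, h, se, np.full(n, 6, int),
                       category=category, anchors=anchors)


def series(midpoints, r, se):
    return RelativeHazardSeries(
        np.asarray(midpoints, float), np.asarray(r, float),
        np.asarray(se, float), np.zeros(len(r), bool), 1, 0,
    )


class TestRatioSeries:
    def test_connecticut_vs_sf_age_67(self, men_curves):
        """285.37 / 218.55 = 1.31 (2 dp) at age 67.5 for men."""
        s = ratio_series(men_curves[1], men_curves[0])
        i = np.where(s.midpoints == 67.5)[0][0]
        assert round(s.r[i], 2) == 1.31

    def test_propagated_se_youngest_group(self, men_curves):
        """h1 = 6.72 +/- 0.62 over h0 = 5.11 +/- 0.50."""
        s = ratio_series(men_curves[1], men_curves[0])
        assert s.r[0] == pytest.approx(6.72 / 5.11, abs=5e-4)
        expected_se = (6.72 / 5.11) * np.sqrt((0.62 / 6.72) ** 2 + (0.50 / 5.11) ** 2)
        assert s.se[0] == pytest.approx(expected_se, abs=1e-4)
        assert s.r[0] == pytest.approx(1.3151, abs=5e-4)
        assert s.se[0] == pytest.approx(0.1769, abs=5e-4)

    def test_self_ratio_is_one_with_sqrt2_relative_se(self, men_curves):
        c = men_curves[0]
        s = ratio_series(c, c)
        np.testing.assert_array_equal(s.r, 1.0)
        np.testing.assert_allclose(
            s.se, np.sqrt(2) * c.se[c.present_mask] / c.h[c.present_mask],
            rtol=1e-12,
        )

    def test_anchor_mismatch_refused(self, men_curves):
        other = curve([37.5, 42.5, 47.5], [1.0, 2.0, 3.0], [0.1, 0.1, 0.1],
                      category=1, anchors=(5, 8))
        with pytest.raises(ValueError, match="anchors"):
            ratio_series(other, men_curves[0])

    def test_ci_bounds_are_plus_minus_196_se(self, men_curves):
        s = ratio_series(men_curves[2], men_curves[0])
        np.testing.assert_allclose(s.ci_low, s.r - 1.96 * s.se, rtol=1e-14)
        np.testing.assert_allclose(s.ci_high, s.r + 1.96 * s.se, rtol=1e-14)

    def test_printed_ratio_tables_reproduced_to_2dp(
        self, men_curves, women_curves
    ):
        """Published per-age relative hazards, both sexes, both contrasts."""
        published = {
            ("men", 1): [1.32, 1.16, 1.35, 1.25, 1.29, 1.28, 1.31, 1.35, 1.35, 1.33, 1.33],
            ("men", 2): [1.44, 1.35, 1.52, 1.64, 1.54, 1.55, 1.56, 1.59, 1.41, 1.45, 1.39],
            ("women", 1): [1.36, 1.77, 1.33, 1.32, 1.25, 1.19, 1.25, 1.19, 1.22, 1.22, 1.08],
            ("women", 2): [1.24, 1.72, 1.54, 1.39, 1.42, 1.33, 1.41, 1.25, 1.23, 1.24, 1.11],
        }
        curves = {"men": men_curves, "women": women_curves}
        for (sex, c), expected in published.items():
            s = ratio_series(curves[sex][c], curves[sex][0])
            assert [round(x, 2) for x in s.r] == expected


class TestFlagOutliers:
    def test_equal_points_unflagged(self):
        s = series([1, 2, 3, 4], [1.5] * 4, [0.1] * 4)
        assert not flag_outliers(s).outlier.any()

    def test_women_connecticut_flags_only_age_42(self, women_curves):
        s = flag_outliers(ratio_series(women_curves[1], women_curves[0]))
        assert s.midpoints[s.outlier].tolist() == [42.5]

    def test_men_detroit_flags_only_age_77(self, men_curves):
        s = flag_outliers(ratio_series(men_curves[2], men_curves[0]))
        assert s.midpoints[s.outlier].tolist() == [77.5]

    def test_men_connecticut_flags_nothing(self, men_curves):
        s = flag_outliers(ratio_series(men_curves[1], men_curves[0]))
        assert not s.outlier.any()

    def test_trend_mode_tolerates_steep_line(self):
        t = np.arange(10, dtype=float)
        s = series(t, 1.0 + 0.05 * t, [0.05] * 10)
        assert not flag_outliers(s, mode="trend").outlier.any()
        assert flag_outliers(s, mode="mean").outlier.any()

    def test_too_few_points_raise(self):
        s = series([1, 2], [1.0, 1.0], [0.1, 0.1])
        with pytest.raises(ValueError, match="at least 3"):
            flag_outliers(s)


class TestAveragedRelativeHazard:
    def test_two_point_weighted_mean(self):
        avg = averaged_relative_hazard(
            series([1, 2], [1.0, 3.0], [1.0, 1.0]), with_slope=False
        )
        assert avg.R == pytest.approx(2.0)
        assert avg.se == pytest.approx(1 / np.sqrt(2))

    def test_equal_values_any_ses(self):
        avg = averaged_relative_hazard(
            series([1, 2, 3], [1.4, 1.4, 1.4], [0.3, 0.1, 0.7])
        )
        assert avg.R == pytest.approx(1.4)
        assert avg.excluded == ()

    def test_men_connecticut_headline_value(self, men_curves):
        """Averaged relative hazard Connecticut vs SF-Oakland, men: 1.31."""
        s = flag_outliers(ratio_series(men_curves[1], men_curves[0]))
        avg = averaged_relative_hazard(s)
        assert round(avg.R, 2) == 1.31

    def test_flagged_points_excluded_from_mean_and_se(self, men_curves):
        s = flag_outliers(ratio_series(men_curves[2], men_curves[0]))
        avg = averaged_relative_hazard(s)
        keep = ~s.outlier
        w = 1 / s.se[keep] ** 2
        assert avg.R == pytest.approx(np.sum(w * s.r[keep]) / np.sum(w), rel=1e-14)
        assert avg.se == pytest.approx(np.sum(w) ** -0.5, rel=1e-14)
        assert avg.excluded == (77.5,)

    def test_se_rescaling_invariance(self):
        """Uniform SE rescaling cancels in R, scales SE[R] linearly."""
        s1 = series([1, 2, 3], [1.1, 1.3, 1.2], [0.1, 0.2, 0.15])
        s2 = series([1, 2, 3], [1.1, 1.3, 1.2], [0.5, 1.0, 0.75])
        a1 = averaged_relative_hazard(s1, with_slope=False)
        a2 = averaged_relative_hazard(s2, with_slope=False)
        assert a2.R == pytest.approx(a1.R, rel=1e-14)
        assert a2.se == pytest.approx(5 * a1.se, rel=1e-14)

    @given(
        st.lists(
            st.tuples(st.floats(0.5, 3.0), st.floats(0.01, 0.5)),
            min_size=3, max_size=11,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_oracle(self, points):
        r = [p[0] for p in points]
        se = [p[1] for p in points]
        avg = averaged_relative_hazard(
            series(np.arange(len(r), dtype=float), r, se), with_slope=False
        )
        num = sum(x / s**2 for x, s in points)
        den = sum(1 / s**2 for _, s in points)
        assert avg.R == pytest.approx(num / den, rel=1e-12)
        assert avg.se == pytest.approx(den**-0.5, rel=1e-12)


class TestWeightedSlope:
    def test_constant_series_has_zero_slope(self):
        b, _ = weighted_slope(series([1, 2, 3, 4], [1.2] * 4, [0.1] * 4))
        assert b == pytest.approx(0.0, abs=1e-14)

    def test_exact_line_interpolated(self):
        t = np.array([40.0, 50.0, 60.0, 70.0])
        b, _ = weighted_slope(series(t, 1.0 + 0.01 * t, [0.1] * 4))
        assert b == pytest.approx(0.01, abs=1e-12)

    def test_men_connecticut_slope(self, men_curves):
        """All-points weighted LS slope vs age: 0.0023 for men Conn vs SF."""
        s = ratio_series(men_curves[1], men_curves[0])
        b, se_b = weighted_slope(s, use_flagged=True)
        assert b == pytest.approx(0.0023, abs=0.0003)

    def test_degenerate_design_raises(self):
        s = series([5.0, 5.0, 5.0], [1.0, 1.1, 1.2], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError, match="degenerate"):
            weighted_slope(s)

    @given(
        st.lists(
            st.tuples(st.floats(0.5, 3.0), st.floats(0.01, 0.5)),
            min_size=3, max_size=11,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_oracle(self, points):
        """Closed-form weighted LS slope agrees to 1e-12."""
        r = np.array([p[0] for p in points])
        se = np.array([p[1] for p in points])
        t = np.arange(len(r), dtype=float)
        b, _ = weighted_slope(series(t, r, se))
        w = 1 / se**2
        tbar = np.sum(w * t) / np.sum(w)
        rbar = np.sum(w * r) / np.sum(w)
        expected = np.sum(w * (t - tbar) * (r - rbar)) / np.sum(w * (t - tbar) ** 2)
        assert b == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestAdjustCurve:
    def test_unit_adjustment_is_identity(self, men_curves):
        c = adjust_curve(men_curves[1], 1.0)
        np.testing.assert_array_equal(c.h, men_curves[1].h)

    def test_scalar_division(self):
        c = curve([40.0], [2.6], [0.2])
        out = adjust_curve(c, 1.3)
        assert out.h[0] == pytest.approx(2.0)
        assert out.se[0] == pytest.approx(0.2 / 1.3)

    def test_adjusted_connecticut_overlays_reference(self, men_curves):
        """After dividing by R the curves differ by <5% over ages 47.5-87.5."""
        s = flag_outliers(ratio_series(men_curves[1], men_curves[0]))
        avg = averaged_relative_hazard(s, with_slope=False)
        adj = adjust_curve(men_curves[1], avg)
        mask = men_curves[0].midpoints >= 47.5
        dev = np.abs(adj.h[mask] / men_curves[0].h[mask] - 1.0)
        assert dev.mean() < 0.05
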