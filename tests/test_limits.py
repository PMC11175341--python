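"""Unit tests for the zeroth-order LOD/LOQ machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import enoselod as el
from enoselod.errors import DesignError, InsufficientBlanksError


class TestKFactor:
    def test_normal_symmetric_005(self):
        k = el.k_factor(0.05, 0.05, "normal")
        assert k.value == pytest.approx(3.2897, abs=1e-4)
        assert f"{k.value:.1f}" == "3.3"

    def test_student_t_nine_blanks(self):
        k = el.k_factor(0.05, 0.05, "student_t", n_blanks=9)
        assert k.value == pytest.approx(2 * 1.8595, abs=1e-3)
        assert k.display() == "3.72"

    def test_inverse_error_probability_at_k3(self):
        # phi-bar(1.5) = 0.0668, commonly quoted as 0.07
        assert el.error_probability(3.0) == pytest.approx(0.0668, abs=1e-4)

    def test_student_t_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="normal"):
            el.k_factor(0.05, 0.01, "student_t", n_blanks=9)

    def test_k_and_error_probability_are_inverses(self):
        for alpha in (0.01, 0.05, 0.1):
            k = el.k_factor(alpha, alpha, "normal")
            assert el.error_probability(k.value) == pytest.approx(alpha, rel=1e-9)

    def test_loq_factor_defaults_to_ten(self):
        k = el.loq_factor()
        assert k.value == 10.0 and k.purpose == "LOQ"


class TestBlankStatistics:
    @pytest.mark.parametrize(
        "values, mean, sd",
        [([5, 5, 5], 5.0, 0.0), ([1, 2, 3], 2.0, 1.0)],
    )
    def test_sample_mean_and_sd(self, values, mean, sd):
        b = el.blank_statistics(values)
        assert b.mean == pytest.approx(mean)
        assert b.sd == pytest.approx(sd)  # N-1 divisor

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientBlanksError):
            el.blank_statistics([1.0])

    def test_signal_threshold(self):
        assert el.signal_threshold(el.blank_statistics([1, 2, 3]), el.KFactorSpec(3.0)) == 5.0
        b = el.BlankStatistics(mean=10.0, sd=0.0, count=3)
        assert el.signal_threshold(b, el.KFactorSpec(3.3)) == 10.0


class TestCalibration:
    def test_exact_line_recovered(self):
        c = np.array([0.0, 1.0, 2.0])
        curve = el.fit_calibration(c, 2 * c + 1)
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(1.0)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-12)
        assert curve.leverage == pytest.approx(1 / 3 + 1 / 2)

    def test_equal_weights_wls_matches_ols(self):
        rng = np.random.default_rng(1)
        c = np.repeat([0.0, 1.0, 2.0, 4.0], 3)
        y = 1.5 * c + rng.normal(0, 0.3, c.size)
        ols = el.fit_calibration(c, y)
        wls = el.fit_calibration(c, y, weighting="wls", weights=np.ones_like(c))
        assert wls.slope == pytest.approx(ols.slope, abs=1e-10)
        assert wls.intercept == pytest.approx(ols.intercept, abs=1e-10)

    def test_wls_beats_ols_under_heteroscedasticity(self):
        """Monte Carlo: reciprocal-variance weighting shrinks slope variance."""
        rng = np.random.default_rng(7)
        c = np.repeat([0.0, 1.0, 2.0, 4.0, 8.0], 4)
        sd = 1.0 + c
        slopes_ols, slopes_wls = [], []
        for _ in range(1000):
            y = 2.0 * c + rng.normal(0, sd)
            slopes_ols.append(el.fit_calibration(c, y).slope)
            slopes_wls.append(
                el.fit_calibration(c, y, weighting="wls", weights=1 / sd**2).slope
            )
        assert np.var(slopes_wls) < np.var(slopes_ols)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(DesignError):
            el.fit_calibration([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(DesignError):
            el.fit_calibration([0.0, 1.0], [0.0, 1.0])


def _curve(slope=2.0, intercept=0.0, conc=(0.0, 1.0, 2.0)):
    c = np.asarray(conc)
    return el.fit_calibration(c, intercept + slope * c)


class TestLodFormulas:
    def test_slope_form_arithmetic(self):
        est = el.lod_from_slope(el.KFactorSpec(3.3), 1.0, _curve(slope=2.0))
        assert est.value == pytest.approx(1.65)
        assert est.valid

    def test_zero_deviation_flagged_degenerate(self):
        est = el.lod_from_slope(el.KFactorSpec(3.3), 0.0, _curve())
        assert est.value == 0.0 and not est.valid

    def test_leverage_linear_and_sqrt_variants(self):
        curve = _curve(slope=1.0)
        # h0 = 1/3 + 1/2 for c in {0,1,2}
        lin = el.lod_with_leverage(el.KFactorSpec(3.3), 1.0, curve, variant="as_printed")
        assert lin.value == pytest.approx(3.3 * (1 + 5 / 6), abs=1e-9)
        sq = el.lod_with_leverage(el.KFactorSpec(3.3), 1.0, curve, variant="sqrt")
        assert sq.value == pytest.approx(3.3 * np.sqrt(1 + 5 / 6), abs=1e-6)
        assert sq.value == pytest.approx(4.468, abs=1e-3)

    def test_leverage_vanishes_for_huge_centered_design(self):
        c = np.concatenate([np.linspace(-1000, 1000, 2000), [0.0]])
        curve = el.fit_calibration(c, 2.0 * c)
        plain = el.lod_from_slope(el.KFactorSpec(3.3), 1.0, curve)
        lev = el.lod_with_leverage(el.KFactorSpec(3.3), 1.0, curve)
        assert lev.value == pytest.approx(plain.value, rel=1e-3)

    def test_adjusted_lod(self):
        # b0 = 2, blank mean 1, m = 1, k*s = 3: unadjusted 3, adjusted 2
        c = np.array([0.0, 1.0, 2.0, 3.0])
        curve = el.fit_calibration(c, 2.0 + c)
        blanks = el.BlankStatistics(mean=1.0, sd=1.0, count=9)
        est = el.adjusted_lod(el.KFactorSpec(3.0), 1.0, curve, blanks)
        assert est.value == pytest.approx(2.0)
        assert est.adjusted

    def test_adjusted_lod_zero_correction_matches_plain(self):
        curve = _curve(slope=2.0, intercept=5.0)
        blanks = el.BlankStatistics(mean=5.0, sd=0.5, count=9)
        adj = el.adjusted_lod(el.KFactorSpec(3.3), 0.5, curve, blanks)
        plain = el.lod_from_slope(el.KFactorSpec(3.3), 0.5, curve)
        assert adj.value == pytest.approx(plain.value)

    def test_adjusted_lod_negative_flagged(self):
        curve = _curve(slope=1.0, intercept=10.0)
        blanks = el.BlankStatistics(mean=1.0, sd=1.0, count=9)
        est = el.adjusted_lod(el.KFactorSpec(3.0), 1.0, curve, blanks)
        assert est.value <= 0 and not est.valid

    def test_negative_slope_uses_magnitude_with_warning(self):
        c = np.array([0.0, 1.0, 2.0])
        curve = el.fit_calibration(c, 4.0 - 2.0 * c)
        with pytest.warns(UserWarning, match="negative"):
            est = el.lod_from_slope(el.KFactorSpec(3.0), 1.0, curve)
        assert est.value == pytest.approx(1.5)

    @given(gamma=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, gamma):
        """Multiplying all signals by gamma leaves the concentration LOD unchanged."""
        rng = np.random.default_rng(0)
        c = np.repeat([0.0, 1.0, 2.0, 4.0], 3)
        y = 2.0 * c + rng.normal(0, 0.2, c.size)
        k = el.KFactorSpec(3.3)
        for y_scaled, scale in ((y, 1.0), (gamma * y, gamma)):
            curve = el.fit_calibration(c, y_scaled)
            s = scale * 0.2
            if scale == 1.0:
                base = el.lod_from_slope(k, s, curve).value
                base_lev = el.lod_with_leverage(k, s, curve).value
            else:
                assert el.lod_from_slope(k, s, curve).value == pytest.approx(base, rel=1e-9)
                assert el.lod_with_leverage(k, s, curve).value == pytest.approx(
                    base_lev, rel=1e-9
                )

    def test_loq_is_lod_times_ten_over_k(self):
        curve = _curve(slope=2.0)
        k = el.k_factor(0.05, 0.05, "normal")
        lod = el.lod_from_slope(k, 1.0, curve)
        loq = el.lod_from_slope(el.loq_factor(), 1.0, curve)
        assert loq.kind == "LOQ"
        assert loq.value / lod.value == pytest.approx(10 / 3.2897072539, abs=1e-6)
        assert loq.value == pytest.approx(5.0)
        lod_lev = el.lod_with_leverage(k, 1.0, curve)
        loq_lev = el.lod_with_leverage(el.loq_factor(), 1.0, curve)
        assert loq_lev.value == pytest.approx(lod_lev.value * 10 / k.value, rel=1e-12)


class TestThresholdScan:
    def test_smallest_exceeding_level(self):
        v = np.array([0.0, 1.0, 1.0, 5.0, 5.0])
        c = np.array([0.0, 1.0, 1.0, 2.0, 2.0])
        scan = el.lowest_exceeding_concentration(v, c, y_lod=3.0)
        assert scan.detected_level == 2.0 and scan.qualifier == ""

    def test_lowest_level_already_exceeding_gives_bound(self):
        scan = el.lowest_exceeding_concentration([0, 4, 5], [0, 1, 2], y_lod=3.0)
        assert scan.detected_level == 1.0 and scan.qualifier == "<"

    def test_nothing_exceeds_gives_sentinel(self):
        scan = el.lowest_exceeding_concentration([0, 1, 2], [0, 1, 2], y_lod=10.0)
        assert not scan.detected and scan.detected_level is None

    def test_no_nonzero_levels_rejected(self):
        with pytest.raises(DesignError):
            el.lowest_exceeding_concentration([1, 2], [0, 0], y_lod=0.0)


def _expected_sd(df: int, sigma: float = 1.0) -> float:
    """Exact finite-sample mean of a chi-based SD estimator with `df` degrees of freedom."""
    from scipy.special import gammaln

    return sigma * np.sqrt(2.0 / df) * np.exp(gammaln((df + 1) / 2) - gammaln(df / 2))


def test_residual_sd_and_blank_sd_estimate_same_sigma():
    """Under a homoscedastic linear truth both SD estimators match their
    exact chi-distribution expectations for sigma = 1 (to Monte Carlo precision)."""
    rng = np.random.default_rng(11)
    c = np.repeat([0.0, 0.5, 1.0, 2.0, 4.0], 9)
    sds_resid, sds_blank = [], []
    for _ in range(300):
        y = 2.0 * c + rng.normal(0, 1.0, c.size)
        sds_resid.append(el.fit_calibration(c, y).residual_sd)
        sds_blank.append(el.blank_statistics(y[c == 0]).sd)
    for sds, df in ((sds_resid, c.size - 2), (sds_blank, 8)):
        se = np.std(sds, ddof=1) / np.sqrt(len(sds))
        assert abs(np.mean(sds) - _expected_sd(df)) < 3 * se
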