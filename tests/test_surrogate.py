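"""Unit tests for surrogate-signal LOD methods."""

import numpy as np
import pytest

import enoselod as el
from enoselod.errors import DesignError, InsufficientBlanksError


def rank1_matrix(conc, loadings, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.outer(conc, loadings)
    if noise_sd:
        X = X + rng.normal(0, noise_sd, X.shape)
    return X


class TestPC1Surrogate:
    def test_rank1_data_fully_explained(self, fm_factory):
        conc = np.repeat([0.0, 1.0, 2.0, 4.0], 3)
        latent = conc - conc.mean()
        fm = fm_factory(rank1_matrix(conc, [1.0, 2.0, 0.5]), conc)
        series = el.pc1_surrogate(fm, variance_floor=0.0)
        assert series.explained_variance_pc1 == pytest.approx(1.0)
        # scores proportional to the (centered) latent variable
        r = np.corrcoef(series.values, latent)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_orientation_independent_of_loading_sign(self, fm_factory):
        conc = np.repeat([0.0, 1.0, 2.0, 4.0], 3)
        a = fm_factory(rank1_matrix(conc, [1.0, 2.0], noise_sd=0.05), conc)
        b = fm_factory(-a.values.to_numpy(), conc)
        sa = el.pc1_surrogate(a, variance_floor=0.0)
        sb = el.pc1_surrogate(b, variance_floor=0.0)
        # either way the scores correlate non-negatively with concentration
        assert np.corrcoef(sa.values, conc)[0, 1] >= 0
        assert np.corrcoef(sb.values, conc)[0, 1] >= 0

    def test_low_explained_variance_warns(self, fm_factory):
        rng = np.random.default_rng(5)
        conc = np.repeat([0.0, 1.0, 2.0], 4)
        fm = fm_factory(rng.normal(0, 1, (12, 6)), conc)
        with pytest.warns(UserWarning, match="PC1 explains"):
            el.pc1_surrogate(fm)

    def test_default_study_has_dominant_pc1(self, study_features):
        series = el.pc1_surrogate(study_features)
        assert series.explained_variance_pc1 > 0.9


def make_series(values, conc, provenance="PCA"):
    values = np.asarray(values, dtype=float)
    conc = np.asarray(conc, dtype=float)
    return el.SurrogateSeries(values=values, concentrations=conc,
                              is_blank=conc == 0, provenance=provenance)


class TestPcaThresholdLod:
    def test_hand_example(self):
        # blank scores {-1, 0, 1}: mean 0, sd 1, k=3 -> threshold 3
        series = make_series([-1, 0, 1, 2, 2, 4, 4], [0, 0, 0, 1, 1, 2, 2])
        est = el.pca_threshold_lod(series, el.KFactorSpec(3.0))
        assert est.value == 2.0 and est.qualifier == ""
        assert est.info["y_lod"] == pytest.approx(3.0)

    def test_lowest_level_exceeding_reports_bound(self):
        series = make_series([-1, 0, 1, 5, 5, 9, 9], [0, 0, 0, 1, 1, 2, 2])
        est = el.pca_threshold_lod(series, el.KFactorSpec(3.0))
        assert est.value == 1.0 and est.qualifier == "<"

    def test_nothing_detected_sentinel(self):
        series = make_series([-1, 0, 1, 1, 1], [0, 0, 0, 1, 1])
        est = el.pca_threshold_lod(series, el.KFactorSpec(3.0))
        assert not est.valid and np.isnan(est.value)

    def test_needs_two_blanks(self):
        series = make_series([0, 1, 2], [0, 1, 2])
        with pytest.raises(InsufficientBlanksError):
            el.pca_threshold_lod(series, el.KFactorSpec(3.0))


class TestPcaCalibrationLod:
    def test_affine_invariance_of_surrogate(self):
        """Ortiz invariance: v -> a*v + b leaves the concentration LOD unchanged."""
        rng = np.random.default_rng(8)
        conc = np.repeat([0.0, 0.5, 1.0, 2.0, 4.0], 3)
        v = 1.7 * conc + rng.normal(0, 0.3, conc.size)
        k = el.k_factor(0.05, 0.05, "normal")
        base = el.pca_calibration_lod(make_series(v, conc), k)
        for a, b in [(3.0, 5.0), (-2.0, 1.0), (0.01, -4.0)]:
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    trans = el.pca_calibration_lod(make_series(a * v + b, conc), k)
            assert trans.value == pytest.approx(base.value, rel=1e-9)
        sblank = el.pca_calibration_lod(make_series(v, conc), k, deviation="s_blank")
        sblank2 = el.pca_calibration_lod(make_series(2 * v + 1, conc), k, deviation="s_blank")
        assert sblank2.value == pytest.approx(sblank.value, rel=1e-9)

    def test_noiseless_line_degenerate(self):
        conc = np.repeat([0.0, 1.0, 2.0], 3)
        est = el.pca_calibration_lod(make_series(2 * conc, conc), el.KFactorSpec(3.3))
        assert est.value == pytest.approx(0.0, abs=1e-9)
        assert not est.valid


class TestComponentSelection:
    def test_rank1_signal_selects_one(self, study_features):
        report = el.select_n_components(study_features, model="PLSR", seed=0)
        assert report.chosen == 1

    def test_rank2_interferent_needs_two(self):
        model = el.SensorModelSpec(interferent_strength=1.0)
        fm = el.zscore_normalize(
            el.subtract_ethanol_reference(el.simulate_features(model, el.StudyDesign(seed=0)))
        )
        for m in ("PLSR", "PCR"):
            report = el.select_n_components(fm, model=m, seed=0)
            assert report.chosen == 2, m

    def test_same_seed_identical_report(self, study_features):
        a = el.select_n_components(study_features, model="PCR", seed=42)
        b = el.select_n_components(study_features, model="PCR", seed=42)
        assert a.chosen_per_repeat == b.chosen_per_repeat
        assert a.mean_rmse == b.mean_rmse

    def test_q2_and_rmse_reported_for_all_candidates(self, study_features):
        report = el.select_n_components(study_features, candidates=[1, 2, 3], seed=1)
        assert set(report.mean_rmse) == {1, 2, 3}
        assert all(q <= 1.0 for q in report.mean_q2.values())


class TestRegressionSurrogateLod:
    def test_noiseless_exact_recovery_degenerate(self, fm_factory):
        conc = np.repeat([0.0, 1.0, 2.0, 4.0], 3)
        fm = fm_factory(rank1_matrix(conc, [1.0, 0.5, 2.0]), conc)
        fm = el.zscore_normalize(fm)
        est = el.regression_surrogate_lod(fm, "PLSR", 1, el.KFactorSpec(3.3))
        assert est.value == pytest.approx(0.0, abs=1e-9)
        assert not est.valid
        series = el.regression_surrogate(fm, "PLSR", 1)
        assert np.allclose(series.values, conc, atol=1e-8)

    def test_components_beyond_rank_rejected(self, fm_factory):
        conc = np.repeat([0.0, 1.0, 2.0], 2)
        fm = fm_factory(rank1_matrix(conc, [1.0, 0.5], noise_sd=0.01), conc)
        with pytest.raises(DesignError):
            el.regression_surrogate_lod(fm, "PCR", 5, el.KFactorSpec(3.3))

    def test_pcr_and_plsr_close_on_single_latent_study(self, study_features):
        k = el.k_factor(0.05, 0.05, "student_t", n_blanks=9)
        pcr = el.regression_surrogate_lod(study_features, "PCR", 1, k)
        plsr = el.regression_surrogate_lod(study_features, "PLSR", 1, k)
        assert plsr.value == pytest.approx(pcr.value, rel=0.25)


class TestCoefficientVector:
    def test_univariate_consistency_with_slope_form(self):
        # J=1, signal = m*c so b = 1/m: 3*s_b/m equals the slope-form LOD at k=3
        m, s_b = 2.0, 0.4
        est = el.coefficient_vector_lod([s_b], [1.0 / m])
        assert est.value == pytest.approx(3.0 * s_b / m)
        assert est.valid

    def test_negative_dominating_sensor_flags_invalid(self):
        est = el.coefficient_vector_lod([5.0, 0.1], [-1.0, 2.0])
        assert est.value < 0 and not est.valid
        assert "negative" in est.reason

    def test_zero_sd_degenerate(self):
        est = el.coefficient_vector_lod([0.0, 0.0], [1.0, 2.0])
        assert est.value == 0.0 and not est.valid

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            el.coefficient_vector_lod([1.0], [1.0, 2.0])

    def test_full_pipeline_coefficients(self, study_features):
        b = el.plsr_coefficients(study_features, 1)
        s = el.per_sensor_blank_sd(study_features)
        est = el.coefficient_vector_lod(s, b)
        assert np.isfinite(est.value)


class TestMRE:
    def _series(self, mre_targets, reps=2):
        # build predictions realizing the requested per-level MRE (in %)
        levels = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        conc, pred = [], []
        for lv, m in zip(levels, mre_targets):
            for _ in range(reps):
                conc.append(lv)
                pred.append(lv * (1 + m / 100.0))
        return make_series(pred, conc, provenance="PLSR(1)")

    def test_change_point_rule_hand_example(self):
        # MRE profile with deltas [63, 5, 0.5, 0.3] -> LOD at the 4th level
        series = self._series([70.0, 7.0, 2.0, 1.5, 1.2])
        profile, est = el.mre_lod(series)
        assert np.allclose(profile.deltas, [63.0, 5.0, 0.5, 0.3])
        assert est.value == 8.0

    def test_all_stable_gives_lowest_level(self):
        series = self._series([1.0, 0.5, 0.8, 0.4, 0.6])
        _, est = el.mre_lod(series)
        assert est.value == 1.0

    def test_never_stable_gives_sentinel(self):
        series = self._series([100.0, 80.0, 60.0, 40.0, 20.0])
        _, est = el.mre_lod(series)
        assert not est.valid and np.isnan(est.value)

    def test_few_levels_flagged_unsuitable(self):
        series = self._series([70.0, 7.0, 2.0, 1.5, 1.2])
        _, est = el.mre_lod(series)
        assert not est.valid or est.info["n_levels"] >= 6

    def test_blanks_rejected(self):
        series = make_series([0.1, 1.0, 2.0, 4.0], [0.0, 1.0, 2.0, 4.0])
        with pytest.raises(DesignError):
            el.mre_lod(el.SurrogateSeries(series.values, series.concentrations,
                                          np.zeros(4, bool), "PLSR(1)"))
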