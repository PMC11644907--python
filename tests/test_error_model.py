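"""Empirical error model: equations, calibration, prediction, correction."""

import numpy as np
import pytest

from wheelmi.error_model import (
    CalibrationError,
    ErrorModelParams,
    ac_rms,
    accel_error,
    apply_correction,
    average_weight_factors,
    calibrate,
    combine_axes,
    fit_correction_factor,
    fit_weight_factor,
    measure_window_error,
    predict_condition_error,
    predict_factor_error,
    total_error,
)
from wheelmi.io_formats import Epoch, RecordingMeta, segment_by_cues
from wheelmi.synthetic import condition_meta, generate_recording

from conftest import one_factor_design


class TestEquations:
    def test_weight_factor_inverts_prediction(self):
        # Wf is defined so that ratio * Wf * E1 reproduces the measurement
        e1, ratio, wf = 3.0, 1.7, 0.8
        e_n = predict_factor_error(e1, ratio, wf, 0.0)
        assert fit_weight_factor(e_n, e1, ratio) == pytest.approx(wf, abs=1e-12)

    def test_prediction_identity_at_reference_level(self):
        # ratio 1, Wf 1, Cf 0 leaves the reference error unchanged
        assert predict_factor_error(2.5, 1.0, 1.0, 0.0) == pytest.approx(2.5, abs=1e-12)

    def test_prediction_linear_in_correction_factor(self):
        base = predict_factor_error(2.0, 1.5, 0.9, 0.0)
        assert predict_factor_error(2.0, 1.5, 0.9, 0.3) == pytest.approx(
            base + 0.3, abs=1e-12
        )

    def test_weight_factor_rejects_zero_reference_error(self):
        with pytest.raises(CalibrationError):
            fit_weight_factor(1.0, 0.0, 1.2)

    def test_weight_factor_rejects_non_positive_ratio(self):
        with pytest.raises(ValueError):
            fit_weight_factor(1.0, 1.0, 0.0)

    def test_average_weight_factors_is_mean(self):
        assert average_weight_factors([0.5, 1.0, 1.5]) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            average_weight_factors([])

    def test_combine_axes_pythagorean(self):
        assert combine_axes(3.0, 4.0, 0.0) == pytest.approx(5.0, abs=1e-12)
        assert combine_axes(1.0, 2.0, 2.0) == pytest.approx(3.0, abs=1e-12)
        assert combine_axes(0.0, 0.0, 0.0) == 0.0

    def test_factor_and_total_averaging(self):
        assert accel_error(1.0, 2.0, 3.0) == pytest.approx(2.0, abs=1e-12)
        assert total_error(1.0, 2.0, 3.0, 4.0) == pytest.approx(2.5, abs=1e-12)

    def test_correction_factor_is_mean_residual(self):
        measured = {"a": 2.0, "b": 3.0}
        predicted = {"a": 1.5, "b": 2.0}
        assert fit_correction_factor(measured, predicted) == pytest.approx(
            0.75, abs=1e-12
        )

    def test_correction_factor_zero_mean_residual_property(self, rng):
        # after subtracting the fitted Cf the hold-out residuals average to 0
        measured = {i: float(v) for i, v in enumerate(rng.normal(size=6))}
        predicted = {i: float(v) for i, v in enumerate(rng.normal(size=6))}
        cf = fit_correction_factor(measured, predicted)
        resid = [measured[k] - (predicted[k] + cf) for k in measured]
        assert np.mean(resid) == pytest.approx(0.0, abs=1e-12)

    def test_correction_factor_requires_matching_keys(self):
        with pytest.raises(ValueError, match="keys differ"):
            fit_correction_factor({"a": 1.0}, {"b": 1.0})
        with pytest.raises(ValueError, match="empty"):
            fit_correction_factor({}, {})


class TestMeasurement:
    def test_ac_rms_removes_offset(self, rng):
        x = rng.normal(size=1000)
        assert ac_rms(x + 100.0) == pytest.approx(ac_rms(x), abs=1e-9)

    def test_ac_rms_of_sine(self):
        t = np.arange(1000) / 250.0
        x = 3.0 * np.sin(2 * np.pi * 5.0 * t)
        assert ac_rms(x) == pytest.approx(3.0 / np.sqrt(2), rel=1e-3)

    def _epoch(self, rng, scale, is_reference=False):
        meta = RecordingMeta(
            73.9, 80.0, "s1", 0.85, is_reference=is_reference
        )
        return Epoch(
            eeg=rng.normal(scale=scale, size=(8, 250)),
            accel=rng.normal(scale=scale / 100, size=(3, 250)),
            label="RELAX",
            fs=250.0,
            meta=meta,
        )

    def test_window_error_is_rms_difference_of_averages(self, rng):
        mot = self._epoch(rng, 5.0)
        ref = self._epoch(rng, 1.0, is_reference=True)
        m = measure_window_error(mot, ref, "eeg_avg")
        expected = ac_rms(mot.eeg.mean(axis=0)) - ac_rms(ref.eeg.mean(axis=0))
        assert m.value == pytest.approx(expected, abs=1e-12)
        assert m.condition == mot.meta

    def test_window_error_accel_axis(self, rng):
        mot = self._epoch(rng, 5.0)
        ref = self._epoch(rng, 1.0, is_reference=True)
        m = measure_window_error(mot, ref, "accel_y")
        assert m.value == pytest.approx(
            ac_rms(mot.accel[1]) - ac_rms(ref.accel[1]), abs=1e-12
        )

    def test_window_error_requires_reference_epoch(self, rng):
        mot = self._epoch(rng, 5.0)
        not_ref = self._epoch(rng, 1.0, is_reference=False)
        with pytest.raises(ValueError, match="reference"):
            measure_window_error(mot, not_ref, "eeg_avg")

    def test_window_error_rejects_unknown_modality(self, rng):
        mot = self._epoch(rng, 5.0)
        ref = self._epoch(rng, 1.0, is_reference=True)
        with pytest.raises(ValueError, match="modality"):
            measure_window_error(mot, ref, "emg")


class TestCalibration:
    def test_noise_free_recovery_is_exact(self, calibration_design, clean_cfg):
        ref, motion = calibration_design
        params = calibrate(ref, motion)
        truth = clean_cfg.true_weight_factors
        for factor in ("surface", "subject", "wheelchair"):
            assert params.weight_factors["eeg_avg"][factor] == pytest.approx(
                truth[factor], abs=1e-6
            )
            assert params.correction_factors["eeg_avg"][factor] == pytest.approx(
                0.0, abs=1e-6
            )

    def test_per_level_weight_factors_agree_noise_free(self, calibration_design):
        ref, motion = calibration_design
        params = calibrate(ref, motion)
        for factor, by_level in params.per_level_weight_factors["eeg_avg"].items():
            vals = list(by_level.values())
            assert np.ptp(vals) < 1e-6

    def test_default_holdouts_are_last_two_levels(self, calibration_design):
        ref, motion = calibration_design
        params = calibrate(ref, motion)
        assert params.holdouts["surface"] == ["s4", "s5"]
        assert len(params.holdouts["subject"]) == 2
        assert len(params.holdouts["wheelchair"]) == 2

    def test_requires_reference_recording(self, calibration_design):
        ref, motion = calibration_design
        with pytest.raises(CalibrationError):
            calibrate(motion[0], motion)

    def test_requires_baseline_motion_cells(self, calibration_design):
        ref, motion = calibration_design
        base = ref.meta
        no_baseline = [
            r
            for r in motion
            if not (
                r.meta.surface_id == base.surface_id
                and r.meta.subject_weight == base.subject_weight
                and r.meta.wheelchair_weight == base.wheelchair_weight
            )
        ]
        with pytest.raises(CalibrationError, match="baseline"):
            calibrate(ref, no_baseline)

    def test_requires_two_levels_per_factor(self, calibration_design):
        ref, motion = calibration_design
        only_one_chair = [
            r for r in motion if r.meta.wheelchair_weight in (80.0, 90.0)
        ]
        with pytest.raises(CalibrationError, match="wheelchair"):
            calibrate(ref, only_one_chair)

    def test_unknown_explicit_holdout_rejected(self, calibration_design):
        ref, motion = calibration_design
        with pytest.raises(CalibrationError, match="hold-out"):
            calibrate(ref, motion, holdouts={"surface": ["s9"]})

    def test_params_json_round_trip(self, calibration_design, tmp_path):
        ref, motion = calibration_design
        params = calibrate(ref, motion)
        path = tmp_path / "params.json"
        params.save(path)
        back = ErrorModelParams.load(path)
        assert back.weight_factors == params.weight_factors
        assert back.normalization == params.normalization
        assert back.holdouts == params.holdouts


class TestPrediction:
    def test_breakdown_contains_all_terms(self, calibration_design, clean_cfg):
        ref, motion = calibration_design
        params = calibrate(ref, motion)
        meta = condition_meta(clean_cfg, "s3")
        out = predict_condition_error(params, meta)
        for key in (
            "eeg_surface", "eeg_subject", "eeg_wheelchair",
            "accel_surface", "accel_subject", "accel_wheelchair",
            "ea", "ea_normalized", "total",
        ):
            assert key in out
        assert out["total"] == pytest.approx(
            (out["eeg_surface"] + out["eeg_subject"] + out["eeg_wheelchair"]
             + out["ea_normalized"]) / 4.0,
            abs=1e-12,
        )

    def test_noise_free_single_factor_prediction_matches_truth(
        self, calibration_design, clean_cfg
    ):
        # for a condition seen in calibration, the per-factor EEG prediction
        # reproduces the injected error: base * (mu1/mun) * Wf_true
        ref, motion = calibration_design
        params = calibrate(ref, motion)
        meta = condition_meta(clean_cfg, "s3")
        ratio = clean_cfg.friction_table["s1"] / clean_cfg.friction_table["s3"]
        expected = clean_cfg.artifact_base_rms_eeg * ratio * 0.8
        out = predict_condition_error(params, meta)
        assert out["eeg_surface"] == pytest.approx(expected, rel=1e-6)


class TestCorrection:
    def test_rms_drops_by_exactly_e_total(self, rng):
        x = rng.normal(size=1000)
        rms = float(np.sqrt(np.mean(x**2)))
        out = apply_correction(x, 0.3 * rms)
        assert float(np.sqrt(np.mean(out**2))) == pytest.approx(0.7 * rms, rel=1e-12)

    def test_non_positive_error_is_identity(self, rng):
        x = rng.normal(size=100)
        np.testing.assert_array_equal(apply_correction(x, 0.0), x)
        np.testing.assert_array_equal(apply_correction(x, -1.0), x)

    def test_error_above_rms_floors_at_zero(self, rng):
        x = rng.normal(size=100)
        rms = float(np.sqrt(np.mean(x**2)))
        np.testing.assert_array_equal(apply_correction(x, 2 * rms), np.zeros(100))

    def test_correction_preserves_waveform_shape(self, rng):
        x = rng.normal(size=500)
        out = apply_correction(x, 0.5)
        # pure rescale: correlation with the input is exactly 1
        assert np.corrcoef(x, out)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_non_finite_error_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_correction(rng.normal(size=10), np.nan)

    def test_corrected_epochs_have_lower_rms_than_uncorrected(self, fast_cfg):
        """End to end: with a positive predicted error, every corrected motion
        epoch's averaged amplitude is strictly below the uncorrected one
        (>= 30 paired epochs)."""
        ref, motion = one_factor_design(fast_cfg, seed=3, trials=2)
        params = calibrate(ref, motion)
        checked = 0
        for rec in motion[:10]:
            e_total = predict_condition_error(params, rec.meta)["total"]
            assert e_total > 0
            for ep in segment_by_cues(rec):
                avg = ep.eeg.mean(axis=0)
                corrected = apply_correction(avg, e_total)
                assert np.sqrt(np.mean(corrected**2)) < np.sqrt(np.mean(avg**2))
                checked += 1
        assert checked >= 30
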