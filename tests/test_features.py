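"""Feature oracles: Hjorth closed forms, Parseval, band powers, moments."""

import numpy as np
import pytest
import pywt

from wheelmi.features import (
    BANDS,
    FEATURE_NAMES,
    FeatureError,
    band_max_powers,
    build_feature_matrix,
    extract_feature_vector,
    extract_features_from_series,
    hjorth_params,
    moment_features,
    wavelet_features,
)
from wheelmi.io_formats import Epoch, RecordingMeta


META = RecordingMeta(73.9, 80.0, "s1", 0.85)


def sine(freq, fs=250.0, n=1250, amp=1.0, phase=0.3):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestHjorth:
    @pytest.mark.parametrize("freq", [2.0, 8.0, 20.0, 40.0])
    def test_sine_mobility_matches_closed_form(self, freq):
        # first-difference mobility of a sampled sinusoid: 2 sin(pi f / fs)
        fs = 250.0
        _, mobility, _ = hjorth_params(sine(freq, fs))
        assert mobility == pytest.approx(2 * np.sin(np.pi * freq / fs), rel=0.01)

    def test_white_noise_mobility_near_sqrt2(self, rng):
        x = rng.normal(size=200_000)
        _, mobility, _ = hjorth_params(x)
        assert mobility == pytest.approx(np.sqrt(2.0), rel=0.02)

    def test_sine_complexity_near_one(self):
        # a pure tone is the minimally complex signal
        _, _, complexity = hjorth_params(sine(10.0))
        assert complexity == pytest.approx(1.0, rel=0.01)

    def test_activity_is_variance(self, rng):
        x = rng.normal(size=5000)
        activity, _, _ = hjorth_params(x)
        assert activity == pytest.approx(np.var(x), rel=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(FeatureError):
            hjorth_params(np.ones(100))


class TestMoments:
    def test_against_brute_force_moments(self, rng):
        for _ in range(10):
            x = rng.normal(loc=rng.uniform(-3, 3), scale=rng.uniform(0.5, 2), size=400)
            mean, mx, var, cv, skew, kurt = moment_features(x)
            n = x.size
            mu = x.sum() / n
            cen = x - mu
            m2 = (cen**2).sum() / n
            m3 = (cen**3).sum() / n
            m4 = (cen**4).sum() / n
            assert mean == pytest.approx(mu, rel=1e-12)
            assert mx == pytest.approx(x.max(), rel=1e-12)
            assert var == pytest.approx((cen**2).sum() / (n - 1), rel=1e-12)
            assert cv == pytest.approx(np.sqrt(var) / abs(mu), rel=1e-12)
            assert skew == pytest.approx(m3 / m2**1.5, rel=1e-9)
            assert kurt == pytest.approx(m4 / m2**2 - 3.0, rel=1e-9)

    def test_gaussian_excess_kurtosis_near_zero(self, rng):
        x = rng.normal(size=500_000)
        *_, kurt = moment_features(x)
        assert abs(kurt) < 0.05

    def test_zero_mean_cv_sentinel(self):
        x = np.array([1.0, -1.0, 2.0, -2.0])
        mean, mx, var, cv, skew, kurt = moment_features(x)
        assert mean == 0.0
        assert cv == np.inf

    def test_zero_variance_rejected(self):
        with pytest.raises(FeatureError):
            moment_features(np.full(10, 3.0))


class TestWavelet:
    def test_parseval_energy_conservation(self, rng):
        # periodization mode conserves energy exactly when the length is
        # divisible by 2^level; otherwise internal padding perturbs it
        x = rng.normal(size=1280)  # 1280 = 16 * 80, exact for level 4
        coeffs = pywt.wavedec(x, "db4", level=4, mode="periodization")
        total = sum(float(np.sum(c**2)) for c in coeffs)
        assert total == pytest.approx(float(np.sum(x**2)), rel=1e-8)
        detail, _ = wavelet_features(x)
        assert detail == pytest.approx(
            sum(float(np.sum(c**2)) for c in coeffs[1:]), rel=1e-12
        )
        # at the pipeline epoch length (1250) conservation is approximate
        y = rng.normal(size=1250)
        coeffs = pywt.wavedec(y, "db4", level=4, mode="periodization")
        total = sum(float(np.sum(c**2)) for c in coeffs)
        assert total == pytest.approx(float(np.sum(y**2)), rel=0.01)

    def test_entropy_bounds(self, rng):
        # Shannon entropy over 4 detail levels lies in [0, ln 4]
        for _ in range(5):
            _, entropy = wavelet_features(rng.normal(size=1250))
            assert 0.0 <= entropy <= np.log(4) + 1e-12

    def test_zero_signal_zero_energy(self):
        energy, entropy = wavelet_features(np.zeros(256))
        assert energy == 0.0 and entropy == 0.0

    def test_too_short_series_rejected(self):
        with pytest.raises(FeatureError):
            wavelet_features(np.ones(4))


class TestBandPowers:
    @pytest.mark.parametrize(
        "freq,band_idx",
        [(2.0, 0), (6.0, 1), (10.0, 2), (20.0, 3)],
    )
    def test_pure_tone_dominates_its_band(self, freq, band_idx):
        powers = band_max_powers(sine(freq), 250.0)
        assert int(np.argmax(powers)) == band_idx
        others = [p for i, p in enumerate(powers) if i != band_idx]
        assert powers[band_idx] > 100 * max(others)

    def test_band_edges(self):
        # 30 Hz belongs to beta (closed upper edge); 13 Hz to beta not alpha
        powers_30 = band_max_powers(sine(30.0), 250.0)
        assert int(np.argmax(powers_30)) == 3
        powers_13 = band_max_powers(sine(13.0), 250.0)
        assert int(np.argmax(powers_13)) == 3

    def test_periodogram_value_of_pure_tone(self):
        # |rfft|^2/n of a unit sine at an exact bin: (n/2)^2 / n = n/4
        n, fs, freq = 1000, 250.0, 10.0
        powers = band_max_powers(sine(freq, fs, n, phase=0.0), fs)
        assert powers[2] == pytest.approx(n / 4.0, rel=1e-9)

    def test_low_fs_rejected(self):
        with pytest.raises(FeatureError, match="beta"):
            band_max_powers(np.ones(100), 50.0)

    def test_window_without_band_bins_rejected(self):
        # a 0.1 s window at 250 Hz has 10 Hz resolution: no delta bin
        with pytest.raises(FeatureError, match="delta"):
            band_max_powers(np.arange(25.0), 250.0)


class TestAssembly:
    def test_vector_has_canonical_names_and_order(self, rng):
        x = rng.normal(size=1250)
        fv = extract_features_from_series(x, 250.0)
        assert fv.names == FEATURE_NAMES
        assert len(FEATURE_NAMES) == 14
        assert fv.values.shape == (14,)
        d = fv.as_dict()
        assert d["variance"] == pytest.approx(np.var(x, ddof=1), rel=1e-12)
        assert d["max"] == pytest.approx(x.max(), rel=1e-12)

    def test_extras_extend_the_vector(self, rng):
        x = rng.normal(size=1250)
        fv = extract_features_from_series(
            x, 250.0, extras={"abs_sum": lambda s: float(np.abs(s).sum())}
        )
        assert fv.names[-1] == "abs_sum"
        assert fv.values[-1] == pytest.approx(np.abs(x).sum())

    def test_epoch_vector_uses_channel_average(self, rng):
        eeg = rng.normal(size=(8, 1250))
        ep = Epoch(eeg=eeg, accel=np.zeros((3, 1250)), label="LEFT", fs=250.0, meta=META)
        fv = extract_feature_vector(ep)
        direct = extract_features_from_series(eeg.mean(axis=0), 250.0)
        np.testing.assert_allclose(fv.values, direct.values, atol=0)
        assert fv.label == "LEFT"

    def test_unknown_source_rejected(self, rng):
        ep = Epoch(
            eeg=rng.normal(size=(8, 1250)),
            accel=np.zeros((3, 1250)),
            label="LEFT",
            fs=250.0,
            meta=META,
        )
        with pytest.raises(ValueError):
            extract_feature_vector(ep, source="denoised")

    def test_feature_matrix_shape_and_subwindow_length(self, rng):
        ep = Epoch(
            eeg=rng.normal(size=(8, 1250)),
            accel=np.zeros((3, 1250)),
            label="RIGHT",
            fs=250.0,
            meta=META,
        )
        fm = build_feature_matrix(ep, n_subwindows=8, overlap_fraction=0.5)
        assert fm.grid.shape == (8, 14)
        assert fm.label == "RIGHT"
        # 8 half-overlapping windows tile 1250 samples with w = floor(1250/4.5)
        assert int(1250 / 4.5) == 277

    def test_feature_matrix_rows_match_subwindow_vectors(self, rng):
        eeg = rng.normal(size=(8, 1250))
        ep = Epoch(eeg=eeg, accel=np.zeros((3, 1250)), label="RELAX", fs=250.0, meta=META)
        fm = build_feature_matrix(ep, n_subwindows=8, overlap_fraction=0.5)
        avg = eeg.mean(axis=0)
        w = int(1250 / 4.5)
        first = extract_features_from_series(avg[:w], 250.0)
        np.testing.assert_allclose(fm.grid[0], first.values, atol=0)

    def test_standardization_with_training_stats(self, rng):
        ep = Epoch(
            eeg=rng.normal(size=(8, 1250)),
            accel=np.zeros((3, 1250)),
            label="RELAX",
            fs=250.0,
            meta=META,
        )
        raw = build_feature_matrix(ep)
        mu = raw.grid.mean(axis=0)
        sigma = raw.grid.std(axis=0)
        standardized = build_feature_matrix(ep, stats=(mu, sigma))
        sigma_safe = np.where(sigma == 0, 1.0, sigma)
        np.testing.assert_allclose(
            standardized.grid, (raw.grid - mu) / sigma_safe, atol=1e-12
        )

    def test_invalid_overlap_rejected(self, rng):
        ep = Epoch(
            eeg=rng.normal(size=(8, 1250)),
            accel=np.zeros((3, 1250)),
            label="RELAX",
            fs=250.0,
            meta=META,
        )
        with pytest.raises(ValueError):
            build_feature_matrix(ep, overlap_fraction=1.0)
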