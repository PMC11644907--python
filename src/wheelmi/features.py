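"""Per-epoch feature extraction for the averaged EEG channel.

Fourteen named features are computed on each (sub-)window of the
channel-averaged series, in this fixed order:

    mobility, complexity, kurtosis, mean, max, coeff_variation, skewness,
    wavelet_detail_energy, wavelet_detail_entropy, variance,
    fft_delta_max_power, fft_theta_max_power, fft_alpha_max_power,
    fft_beta_max_power

Hjorth mobility/complexity use first differences; kurtosis is excess;
coefficient of variation uses |mean|; the wavelet features come from a
Daubechies-4 decomposition (level 4, periodization mode, which conserves
energy exactly); band max powers are the maximum of the unwindowed
periodogram ``|FFT(x - mean)|^2 / n`` within the clinical bands delta
0.5-4, theta 4-8, alpha 8-13, beta 13-30 Hz.

For the CNN the epoch is split into overlapping sub-windows (default 8 at
50% overlap) and the per-sub-window vectors are stacked into a 2-D
n_subwindows x n_features grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pywt
import scipy.stats

from .io_formats import Epoch
from .reshape import reshape1

__all__ = [
    "FEATURE_NAMES",
    "BANDS",
    "FeatureError",
    "FeatureVector",
    "FeatureMatrix",
    "hjorth_params",
    "moment_features",
    "wavelet_features",
    "band_max_powers",
    "extract_features_from_series",
    "extract_feature_vector",
    "build_feature_matrix",
]

FEATURE_NAMES = (
    "mobility",
    "complexity",
    "kurtosis",
    "mean",
    "max",
    "coeff_variation",
    "skewness",
    "wavelet_detail_energy",
    "wavelet_detail_entropy",
    "variance",
    "fft_delta_max_power",
    "fft_theta_max_power",
    "fft_alpha_max_power",
    "fft_beta_max_power",
)

#: Clinical EEG bands, Hz: [low, high) except beta which includes 30 Hz.
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

WAVELET = "db4"
WAVELET_LEVEL = 4


class FeatureError(ValueError):
    """A feature cannot be computed on this window (degenerate input)."""


@dataclass(frozen=True)
class FeatureVector:
    """One window's features, in :data:`FEATURE_NAMES` order."""

    values: np.ndarray
    label: str | None = None
    names: tuple[str, ...] = FEATURE_NAMES

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


@dataclass(frozen=True)
class FeatureMatrix:
    """n_subwindows x n_features grid, the 2-D input of the CNN."""

    grid: np.ndarray
    label: str | None = None
    names: tuple[str, ...] = FEATURE_NAMES


# ---------------------------------------------------------------------------
# Individual feature groups
# ---------------------------------------------------------------------------

def hjorth_params(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity of a series.

    activity = var(x); mobility = sqrt(var(dx)/var(x)) is an RMS-frequency
    proxy; complexity = mobility(dx)/mobility(x) is a bandwidth proxy.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise FeatureError("hjorth_params needs at least 3 samples")
    var_x = float(np.var(x))
    if var_x == 0.0:
        raise FeatureError("hjorth_params: degenerate (constant) series")
    dx = np.diff(x)
    var_dx = float(np.var(dx))
    ddx = np.diff(dx)
    var_ddx = float(np.var(ddx))
    mobility = np.sqrt(var_dx / var_x)
    if var_dx == 0.0:
        raise FeatureError("hjorth_params: first differences are constant")
    complexity = np.sqrt(var_ddx / var_dx) / mobility
    return var_x, float(mobility), float(complexity)


def moment_features(
    x: np.ndarray, cv_zero_mean: float = np.inf
) -> tuple[float, float, float, float, float, float]:
    """(mean, max, variance, coeff_variation, skewness, excess kurtosis).

    Variance is the unbiased sample variance; CV = std/|mean| (a zero mean
    yields the configured sentinel); skewness and kurtosis are standardized
    central moments (kurtosis is excess, i.e. 0 for a Gaussian).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise FeatureError("moment_features needs at least 4 samples")
    mean = float(np.mean(x))
    mx = float(np.max(x))
    variance = float(np.var(x, ddof=1))
    std = np.sqrt(variance)
    cv = std / abs(mean) if mean != 0.0 else float(cv_zero_mean)
    if variance == 0.0:
        raise FeatureError("moment_features: zero variance, skew/kurtosis undefined")
    skewness = float(scipy.stats.skew(x, bias=True))
    kurtosis = float(scipy.stats.kurtosis(x, fisher=True, bias=True))
    return mean, mx, variance, cv, skewness, kurtosis


def wavelet_features(x: np.ndarray) -> tuple[float, float]:
    """(detail_energy, detail_entropy) of the wavelet decomposition.

    detail_energy sums the squared detail coefficients over all levels;
    detail_entropy is the Shannon entropy (natural log, 0*log0 = 0) of the
    per-level relative detail energies.
    """
    x = np.asarray(x, dtype=float)
    wav = pywt.Wavelet(WAVELET)
    if x.size < wav.dec_len:
        raise FeatureError(
            f"wavelet_features needs at least {wav.dec_len} samples, got {x.size}"
        )
    level = min(WAVELET_LEVEL, pywt.dwt_max_level(x.size, wav.dec_len))
    coeffs = pywt.wavedec(x, wav, level=level, mode="periodization")
    detail_energies = np.array([float(np.sum(d**2)) for d in coeffs[1:]])
    total = float(detail_energies.sum())
    if total == 0.0:
        return 0.0, 0.0
    p = detail_energies / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return total, entropy


def band_max_powers(x: np.ndarray, fs: float) -> tuple[float, float, float, float]:
    """Maximum periodogram value inside each clinical band.

    The periodogram is the unwindowed ``|rfft(x - mean)|^2 / n``.  Raises
    :class:`FeatureError` if fs cannot cover the beta band (fs < 60) or if a
    band contains no frequency bin at this window length.
    """
    x = np.asarray(x, dtype=float)
    if fs < 60.0:
        raise FeatureError(f"fs={fs} too low to resolve the beta band (needs >= 60)")
    if x.size < 2:
        raise FeatureError("band_max_powers needs at least 2 samples")
    n = x.size
    p = np.abs(np.fft.rfft(x - x.mean())) ** 2 / n
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    out = []
    for name, (lo, hi) in BANDS.items():
        mask = (f >= lo) & ((f <= hi) if name == "beta" else (f < hi))
        if not mask.any():
            raise FeatureError(
                f"band {name} ({lo}-{hi} Hz) has no frequency bin at n={n}, fs={fs}"
            )
        out.append(float(p[mask].max()))
    return tuple(out)


# ---------------------------------------------------------------------------
# Vector / matrix assembly
# ---------------------------------------------------------------------------

def extract_features_from_series(
    x: np.ndarray,
    fs: float,
    label: str | None = None,
    extras: Mapping[str, Callable[[np.ndarray], float]] | None = None,
) -> FeatureVector:
    """Compute the full feature vector on a single-channel series.

    ``extras`` optionally appends named features (e.g. to extend the vector
    from the 14 defaults to a configured length).  Degenerate windows raise
    :class:`FeatureError` naming the failing feature group.
    """
    x = np.asarray(x, dtype=float)
    try:
        _, mobility, complexity = hjorth_params(x)
        mean, mx, variance, cv, skewness, kurtosis = moment_features(x)
        w_energy, w_entropy = wavelet_features(x)
        delta, theta, alpha, beta = band_max_powers(x, fs)
    except FeatureError:
        raise
    values = [
        mobility, complexity, kurtosis, mean, mx, cv, skewness,
        w_energy, w_entropy, variance, delta, theta, alpha, beta,
    ]
    names = list(FEATURE_NAMES)
    if extras:
        for name, fn in extras.items():
            names.append(name)
            values.append(float(fn(x)))
    return FeatureVector(values=np.array(values), label=label, names=tuple(names))


def extract_feature_vector(epoch: Epoch, source: str = "raw_avg") -> FeatureVector:
    """Feature vector of one epoch, computed on the channel-averaged series.

    ``source='raw_avg'`` averages the epoch's EEG as stored;
    ``source='corrected_avg'`` is identical but documents that the epoch's
    channels already carry the error-model correction (the correction is
    applied upstream, before the epoch is re-expanded to 8 channels).
    """
    if source not in ("raw_avg", "corrected_avg"):
        raise ValueError(f"unknown source {source!r}")
    avg, _ = reshape1(epoch.eeg)
    return extract_features_from_series(avg, epoch.fs, label=epoch.label)


def _subwindow_bounds(n: int, n_subwindows: int, overlap_fraction: float) -> list[tuple[int, int]]:
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if n_subwindows < 1:
        raise ValueError("n_subwindows must be >= 1")
    # window length w satisfying (n_subwindows-1) hops of w*(1-overlap) + w = n
    denom = n_subwindows * (1.0 - overlap_fraction) + overlap_fraction
    w = int(n / denom)
    if w < 2:
        raise ValueError("sub-windows too short for this epoch length")
    hop = w * (1.0 - overlap_fraction)
    starts = [int(round(i * hop)) for i in range(n_subwindows)]
    return [(s, min(s + w, n)) for s in starts]


def build_feature_matrix(
    epoch: Epoch,
    n_subwindows: int = 8,
    overlap_fraction: float = 0.5,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
    source: str = "raw_avg",
) -> FeatureMatrix:
    """Stack per-sub-window feature vectors into the CNN's 2-D input.

    The epoch's averaged series is split into ``n_subwindows`` overlapping
    windows; row i is the feature vector of window i.  If ``stats`` (per-
    feature mean and std, computed by the caller on the training set) is
    given, columns are standardized with them.
    """
    if source not in ("raw_avg", "corrected_avg"):
        raise ValueError(f"unknown source {source!r}")
    avg, _ = reshape1(epoch.eeg)
    bounds = _subwindow_bounds(avg.size, n_subwindows, overlap_fraction)
    rows = [
        extract_features_from_series(avg[i0:i1], epoch.fs).values for i0, i1 in bounds
    ]
    grid = np.vstack(rows)
    if stats is not None:
        mu, sigma = stats
        sigma = np.where(np.asarray(sigma) == 0.0, 1.0, sigma)
        grid = (grid - mu) / sigma
    if not np.isfinite(grid).all():
        raise FeatureError("feature matrix contains non-finite values")
    return FeatureMatrix(grid=grid, label=epoch.label)
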