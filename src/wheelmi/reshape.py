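"""Data reshaping between 8-channel and single-channel EEG.

The artifact-correction stage operates on a single averaged channel.  Reshape
step 1 collapses the 8 channels to their per-sample mean (E_avg) and records
per-channel weights; reshape step 2 re-expands a corrected single-channel
series back to 8 channels using those weights.

Channel weights are each channel's RMS share, normalized to mean 1:
``w_c = RMS(channel c) / mean_c(RMS)``.  This makes the round trip exact:
averaging the reshape-2 output recovers the corrected series bit-for-bit,
and the weights preserve the relative channel amplitude structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChannelWeights", "reshape1", "reshape2"]


@dataclass(frozen=True)
class ChannelWeights:
    """Per-epoch channel weights (mean exactly 1, all >= 0).

    ``degenerate`` flags an all-zero window, for which the weights fall back
    to all-ones.
    """

    weights: np.ndarray  # (8,)
    degenerate: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (8,):
            raise ValueError("weights must have shape (8,)")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")


def reshape1(eeg: np.ndarray) -> tuple[np.ndarray, ChannelWeights]:
    """Average an 8 x n EEG window to one channel and compute channel weights.

    Returns ``(avg, weights)`` where ``avg[t]`` is the plain per-sample mean
    across channels and ``weights`` carries each channel's RMS share
    (normalized so the weights average exactly 1).
    """
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim != 2 or eeg.shape[0] != 8:
        raise ValueError(f"expected an 8 x n window, got shape {eeg.shape}")
    if eeg.shape[1] < 2:
        raise ValueError("window must have at least 2 samples")
    if not np.isfinite(eeg).all():
        raise ValueError("window contains non-finite samples")
    avg = eeg.mean(axis=0)
    rms = np.sqrt(np.mean(eeg**2, axis=1))
    mean_rms = rms.mean()
    if mean_rms == 0.0:
        return avg, ChannelWeights(np.ones(8), degenerate=True)
    w = rms / mean_rms
    # enforce mean(w) == 1 to the last bit
    w = w / w.mean()
    return avg, ChannelWeights(w)


def reshape2(corrected: np.ndarray, weights: ChannelWeights) -> np.ndarray:
    """Expand a corrected single-channel series back to 8 channels.

    ``out[c, t] = weights[c] * corrected[t]``; because the weights average to
    1, the channel mean of the output equals ``corrected`` exactly.
    """
    corrected = np.asarray(corrected, dtype=float)
    if corrected.ndim != 1:
        raise ValueError(f"corrected series must be 1-D, got shape {corrected.shape}")
    return weights.weights[:, None] * corrected[None, :]
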