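"""Synthetic EEG + accelerometer recordings with known artifact structure.

Every downstream stage (reshaping, error calibration, feature extraction,
classification) is exercised on generated data, because the measured
wheelchair recordings this pipeline targets are private.  The generator
emulates:

* band-limited Gaussian background EEG (default 1-40 Hz) per channel;
* cue-locked class signatures: LEFT adds a 12 Hz (mu/alpha) burst and RIGHT
  a 20 Hz (beta) burst, both lateralized over the motor electrodes C3/C4
  with asymmetric amplitudes, RELAX stays unmodulated — chosen so the
  8-channel *average* (on which all features are computed) is
  class-informative;
* additive motion artifacts: band-limited (default 0.5-10 Hz) vibration
  injected identically into all 8 EEG channels and, with its own base
  amplitude, into the 3 accelerometer axes;
* multiplicative gain instability: vibration also perturbs the
  electrode-skin interface, so in motion conditions the *clean* EEG
  (background + signatures) is amplified by ``1 + gain_instability * p(c)``
  with the same condition multiplier ``p`` as the additive artifact.  This
  is the component an RMS-shrinkage correction can genuinely undo: it makes
  the class-relevant feature amplitudes condition-dependent until the
  predicted error is removed.

Artifact amplitudes follow the empirical error-model law.  A stationary
reference recording carries vibration at exactly the base RMS; a motion
recording at condition c carries ``base * (1 + p(c))`` where

    p(c) = m_surface * m_subject * m_wheelchair,
    m_factor = 1 at the factor's reference level,
               (ref_level / level) * Wf_factor_true otherwise,

so the measured error (motion RMS minus reference RMS) equals
``base * p(c)`` — the multiplicative form the error model assumes — exactly.
Vibration is mean-removed and renormalized inside every 5-s cue window, so
with the background and class amplitudes set to zero the calibration
recovers the generating weight factors to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    DEFAULT_MONTAGE,
    CueSchedule,
    Recording,
    RecordingMeta,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "condition_meta",
    "reference_meta",
    "artifact_multiplier",
    "generate_recording",
    "generate_condition_grid",
]


def _default_signatures() -> dict:
    # (frequency Hz, amplitude uV, per-channel gains); lateralized C3/C4
    return {
        "RELAX": (),
        "LEFT": (((12.0, 15.0, {"C4": 1.0, "C3": 0.4})),),
        "RIGHT": (((20.0, 15.0, {"C3": 1.0, "C4": 0.4})),),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration (defaults define the study conditions).

    Amplitudes are per-channel RMS in uV (EEG) and g (accelerometer).
    ``true_weight_factors`` are the ground-truth Wf values the calibration
    is expected to recover.  ``friction_table`` ships plausible tire-surface
    coefficients (the study's own table is unusable); the first surface /
    subject weight / wheelchair weight is the reference level of its factor.
    """

    fs: float = 250.0
    n_trials_per_class: int = 3
    class_labels: tuple[str, ...] = ("RELAX", "LEFT", "RIGHT")
    background_band: tuple[float, float] = (1.0, 40.0)
    class_signatures: Mapping = field(default_factory=_default_signatures)
    artifact_base_rms_eeg: float = 20.0  # uV
    artifact_base_rms_accel: float = 0.05  # g
    artifact_band: tuple[float, float] = (0.5, 10.0)
    true_weight_factors: Mapping[str, float] = field(
        default_factory=lambda: {"surface": 1.0, "subject": 1.0, "wheelchair": 1.0}
    )
    friction_table: Mapping[str, float] = field(
        default_factory=lambda: {"s1": 0.85, "s2": 0.75, "s3": 0.65, "s4": 0.55, "s5": 0.45}
    )
    subject_weights: tuple[float, ...] = (73.9, 81.0, 85.0, 82.0, 78.3)
    wheelchair_weights: tuple[float, ...] = (80.0, 90.0, 25.0)
    noise_rms: float = 10.0  # background EEG RMS per channel, uV
    accel_noise_rms: float = 0.005  # accelerometer sensor noise, g
    gain_instability: float = 0.3  # clean-EEG gain slope vs the condition multiplier
    n_trials: int = 3  # repeats per grid cell
    epoch_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("artifact_base_rms_eeg", "artifact_base_rms_accel",
                     "noise_rms", "accel_noise_rms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        missing = [l for l in self.class_labels if l not in self.class_signatures]
        if missing:
            raise ValueError(f"class_signatures missing labels: {missing}")

    @property
    def reference_surface(self) -> str:
        return next(iter(self.friction_table))


@dataclass
class GroundTruth:
    """What the generator injected: the artifact series and the true model."""

    eeg_artifact: np.ndarray  # (n,) uV, identical in every channel
    accel_vibration: np.ndarray  # (3, n) g
    eeg_artifact_rms: float  # per-epoch target RMS, uV
    accel_vibration_rms: float  # per-epoch target RMS per axis, g
    multiplier: float  # p(c); by convention 1.0 for the reference session
    clean_gain: float  # gain applied to the clean EEG (1.0 when stationary)
    true_weight_factors: dict
    meta: RecordingMeta


# ---------------------------------------------------------------------------
# Conditions
# ---------------------------------------------------------------------------

def condition_meta(
    cfg: SynthConfig,
    surface_id: str,
    subject_idx: int = 0,
    wheelchair_idx: int = 0,
    trial: int = 0,
) -> RecordingMeta:
    """Metadata for a motion condition drawn from the configured tables."""
    if surface_id not in cfg.friction_table:
        raise ValueError(f"unknown surface_id {surface_id!r}")
    return RecordingMeta(
        subject_weight=cfg.subject_weights[subject_idx],
        wheelchair_weight=cfg.wheelchair_weights[wheelchair_idx],
        surface_id=surface_id,
        friction=cfg.friction_table[surface_id],
        wheelchair_id=f"u{wheelchair_idx + 1}",
        is_reference=False,
        trial=trial,
    )


def reference_meta(cfg: SynthConfig) -> RecordingMeta:
    """Metadata of the stationary baseline session (all factors at reference)."""
    s = cfg.reference_surface
    return RecordingMeta(
        subject_weight=cfg.subject_weights[0],
        wheelchair_weight=cfg.wheelchair_weights[0],
        surface_id=s,
        friction=cfg.friction_table[s],
        wheelchair_id="u1",
        is_reference=True,
    )


def artifact_multiplier(cfg: SynthConfig, meta: RecordingMeta) -> float:
    """p(c): product of per-factor multipliers (1 at each reference level)."""
    wf = cfg.true_weight_factors
    p = 1.0
    ref_mu = cfg.friction_table[cfg.reference_surface]
    if meta.surface_id != cfg.reference_surface:
        p *= (ref_mu / meta.friction) * wf["surface"]
    if meta.subject_weight != cfg.subject_weights[0]:
        p *= (cfg.subject_weights[0] / meta.subject_weight) * wf["subject"]
    if meta.wheelchair_weight != cfg.wheelchair_weights[0]:
        p *= (cfg.wheelchair_weights[0] / meta.wheelchair_weight) * wf["wheelchair"]
    return p


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------

def _band_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float], rms: float
) -> np.ndarray:
    """Zero-mean Gaussian noise band-limited by FFT masking, renormalized to
    the exact target RMS."""
    if rms == 0.0 or n == 0:
        return np.zeros(n)
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    y = np.fft.irfft(spec, n)
    y -= y.mean()
    cur = np.sqrt(np.mean(y**2))
    if cur == 0.0:
        return np.zeros(n)
    return y * (rms / cur)


def _channel_gains(gains: Mapping[str, float]) -> np.ndarray:
    g = np.zeros(8)
    for name, a in gains.items():
        g[DEFAULT_MONTAGE.index(name)] = a
    return g


# ---------------------------------------------------------------------------
# Recording generation
# ---------------------------------------------------------------------------

def _default_schedule(cfg: SynthConfig) -> CueSchedule:
    if "LEFT" in cfg.class_labels or "RIGHT" in cfg.class_labels:
        return CueSchedule.interleaved(cfg.n_trials_per_class, cfg.epoch_s)
    return CueSchedule.relax_only(cfg.n_trials_per_class, cfg.epoch_s)


def generate_recording(
    cfg: SynthConfig,
    condition: RecordingMeta,
    seed: int | np.random.SeedSequence,
    schedule: CueSchedule | None = None,
) -> tuple[Recording, GroundTruth]:
    """Generate one recording for ``condition`` plus its ground truth.

    The same ``cfg``, ``condition`` and ``seed`` always reproduce the output
    bit for bit.  The motion artifact is injected epoch-by-epoch with its
    RMS pinned exactly to the condition's target amplitude.
    """
    if condition.surface_id not in cfg.friction_table:
        raise ValueError(f"unknown surface_id {condition.surface_id!r}")
    if schedule is None:
        schedule = _default_schedule(cfg)
    if len(schedule) == 0:
        raise ValueError("empty cue schedule")
    rng = np.random.default_rng(seed)
    fs = cfg.fs
    end_s = max(e.start_s + e.duration_s for e in schedule)
    n = int(round(end_s * fs))

    p = 1.0 if condition.is_reference else artifact_multiplier(cfg, condition)
    eeg_target = cfg.artifact_base_rms_eeg * (1.0 if condition.is_reference else 1.0 + p)
    accel_target = cfg.artifact_base_rms_accel * (
        1.0 if condition.is_reference else 1.0 + p
    )
    # electrode gain instability scales with the same motion multiplier; it
    # vanishes for the stationary session and in the artifact-free limit
    if condition.is_reference or cfg.artifact_base_rms_eeg == 0.0:
        gain = 1.0
    else:
        gain = 1.0 + cfg.gain_instability * p

    eeg = np.empty((8, n))
    for c in range(8):
        eeg[c] = _band_noise(rng, n, fs, cfg.background_band, cfg.noise_rms)

    t = np.arange(n) / fs
    eeg_artifact = np.zeros(n)
    accel_vib = np.zeros((3, n))
    for entry in schedule:
        i0 = int(round(entry.start_s * fs))
        i1 = i0 + int(round(entry.duration_s * fs))
        # cue-locked class signature with a random phase per epoch
        for freq, amp, gains in cfg.class_signatures.get(entry.label, ()):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            wave = np.sqrt(2.0) * amp * np.sin(2.0 * np.pi * freq * t[i0:i1] + phase)
            eeg[:, i0:i1] += _channel_gains(gains)[:, None] * wave[None, :]
        # motion artifact, exact per-epoch RMS, common to all EEG channels
        a = _band_noise(rng, i1 - i0, fs, cfg.artifact_band, eeg_target)
        eeg_artifact[i0:i1] = a
        for axis in range(3):
            accel_vib[axis, i0:i1] = _band_noise(
                rng, i1 - i0, fs, cfg.artifact_band, accel_target
            )
    eeg *= gain
    eeg += eeg_artifact[None, :]

    accel = accel_vib.copy()
    accel[2] += 1.0  # gravity on the z axis, g
    if cfg.accel_noise_rms > 0:
        accel += rng.normal(0.0, cfg.accel_noise_rms, size=(3, n))

    rec = Recording(eeg=eeg, accel=accel, fs=fs, cues=schedule, meta=condition)
    gt = GroundTruth(
        eeg_artifact=eeg_artifact,
        accel_vibration=accel_vib,
        eeg_artifact_rms=eeg_target,
        accel_vibration_rms=accel_target,
        multiplier=p,
        clean_gain=gain,
        true_weight_factors=dict(cfg.true_weight_factors),
        meta=condition,
    )
    return rec, gt


def generate_condition_grid(
    cfg: SynthConfig, seed: int | None = None
) -> list[tuple[Recording, GroundTruth]]:
    """One stationary reference recording plus one motion recording per
    (surface, subject, wheelchair, trial) cell of the configured design.

    The first returned pair is the reference.  Cells get independent child
    seeds spawned from ``seed`` (default ``cfg.seed``), so the grid is
    reproducible as a whole while cells remain statistically independent.
    """
    if not cfg.friction_table or not cfg.subject_weights or not cfg.wheelchair_weights:
        raise ValueError("grid requires at least one surface, subject and wheelchair")
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    n_cells = (
        len(cfg.friction_table) * len(cfg.subject_weights) * len(cfg.wheelchair_weights)
        * cfg.n_trials
    )
    children = root.spawn(n_cells + 1)
    out: list[tuple[Recording, GroundTruth]] = []
    out.append(generate_recording(cfg, reference_meta(cfg), children[0]))
    i = 1
    for surface_id in cfg.friction_table:
        for s_idx in range(len(cfg.subject_weights)):
            for w_idx in range(len(cfg.wheelchair_weights)):
                for trial in range(cfg.n_trials):
                    meta = condition_meta(cfg, surface_id, s_idx, w_idx, trial)
                    out.append(generate_recording(cfg, meta, children[i]))
                    i += 1
    return out
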