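"""Empirical motion-error model: calibration, prediction, and correction.

The model quantifies how much wheelchair motion inflates the signal amplitude
relative to a stationary reference session.  "Error" is the difference in
AC-coupled RMS between a motion epoch and a reference epoch, measured per
modality (each accelerometer axis in g, and the averaged EEG channel in uV).

Three physical factors drive the error: terrain friction (mu), subject weight
(W), and wheelchair weight (U).  For each factor the error at a non-reference
level n is modelled as

    E_n = ratio_n * Wf * E_1 + Cf

where ``ratio_n`` is mu_1/mu_n (surface), W_1/W_n (subject) or U_1/U_n
(wheelchair), ``E_1`` is the error measured at the factor's reference level,
``Wf`` is a fitted multiplicative weight factor (the average of the
per-level fits), and ``Cf`` is a second-level additive correction factor:
the mean residual (measured - predicted) on designated hold-out levels.

Axis errors combine Euclidean-style into one accelerometer error per factor;
the three factor errors average into Ea.  The total EEG-scale error averages
the three EEG factor errors with Ea (rescaled to EEG units), and is removed
from the averaged EEG channel by RMS shrinkage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import Epoch, Recording, segment_by_cues
from .reshape import reshape1

__all__ = [
    "MODALITIES",
    "FACTORS",
    "CalibrationError",
    "ErrorMeasurement",
    "ErrorModelParams",
    "ac_rms",
    "measure_window_error",
    "fit_weight_factor",
    "average_weight_factors",
    "fit_correction_factor",
    "predict_factor_error",
    "combine_axes",
    "accel_error",
    "total_error",
    "calibrate",
    "predict_condition_error",
    "apply_correction",
]

MODALITIES = ("accel_x", "accel_y", "accel_z", "eeg_avg")
ACCEL_MODALITIES = ("accel_x", "accel_y", "accel_z")
FACTORS = ("surface", "subject", "wheelchair")


class CalibrationError(ValueError):
    """The calibration design is incomplete or degenerate."""


def ac_rms(x: np.ndarray) -> float:
    """Root-mean-square after removing the window mean (AC-coupled).

    Mean removal keeps the accelerometer gravity offset (and any EEG DC
    drift) out of the motion-error measurement.
    """
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


@dataclass(frozen=True)
class ErrorMeasurement:
    """One windowed error observation: RMS(motion) - RMS(reference)."""

    modality: str
    value: float  # g for accel modalities, uV for eeg_avg
    condition: object = None  # RecordingMeta of the motion epoch
    epoch_id: int | None = None


def _modality_signal(epoch: Epoch, modality: str) -> np.ndarray:
    if modality == "eeg_avg":
        avg, _ = reshape1(epoch.eeg)
        return avg
    try:
        axis = ACCEL_MODALITIES.index(modality)
    except ValueError:
        raise ValueError(f"unknown modality {modality!r}") from None
    return epoch.accel[axis]


def measure_window_error(
    motion: Epoch, reference: Epoch, modality: str
) -> ErrorMeasurement:
    """Error of one motion epoch against one reference epoch.

    value = AC-RMS(motion signal) - AC-RMS(reference signal), where the
    signal is the selected accelerometer axis or the channel-averaged EEG.
    """
    if motion.fs != reference.fs:
        raise ValueError("motion and reference epochs must share fs")
    if motion.n_samples != reference.n_samples:
        raise ValueError("motion and reference epochs must share length")
    if not reference.meta.is_reference:
        raise ValueError("reference epoch must come from a reference recording")
    value = ac_rms(_modality_signal(motion, modality)) - ac_rms(
        _modality_signal(reference, modality)
    )
    return ErrorMeasurement(modality=modality, value=value, condition=motion.meta)


def _value(x) -> float:
    return float(x.value) if isinstance(x, ErrorMeasurement) else float(x)


def fit_weight_factor(measured_n, reference_1, ratio: float) -> float:
    """Weight factor making ``E_n = ratio * Wf * E_1`` exact for one level."""
    e_n, e_1 = _value(measured_n), _value(reference_1)
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    if e_1 == 0.0:
        raise CalibrationError("zero reference error: cannot normalize weight factor")
    return e_n / (ratio * e_1)


def average_weight_factors(factors: Sequence[float]) -> float:
    """Arithmetic mean of per-level weight factors (the model's general Wf)."""
    if len(factors) == 0:
        raise ValueError("cannot average an empty list of weight factors")
    return float(np.mean([float(f) for f in factors]))


def fit_correction_factor(
    measured_holdout: Mapping, predicted_holdout: Mapping
) -> float:
    """Second-level correction: mean (measured - predicted) over hold-outs."""
    if set(measured_holdout) != set(predicted_holdout):
        raise ValueError(
            f"hold-out condition keys differ: {sorted(map(str, measured_holdout))} "
            f"vs {sorted(map(str, predicted_holdout))}"
        )
    if not measured_holdout:
        raise ValueError("hold-out set is empty")
    resid = [
        _value(measured_holdout[k]) - _value(predicted_holdout[k])
        for k in measured_holdout
    ]
    return float(np.mean(resid))


def predict_factor_error(
    reference_error: float, ratio: float, wf: float, cf: float
) -> float:
    """General per-factor prediction: ``ratio * wf * reference_error + cf``."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    return ratio * wf * reference_error + cf


def combine_axes(ex: float, ey: float, ez: float) -> float:
    """Euclidean combination of the three accelerometer-axis errors."""
    return float(np.sqrt(ex * ex + ey * ey + ez * ez))


def accel_error(e_surface: float, e_subject: float, e_wheelchair: float) -> float:
    """Overall accelerometer error Ea: mean of the three factor errors."""
    return (e_surface + e_subject + e_wheelchair) / 3.0


def total_error(esn: float, epn: float, ewn: float, ea_normalized: float) -> float:
    """Total EEG-scale error: mean of the three EEG factor errors and the
    (EEG-unit-normalized) accelerometer error."""
    return (esn + epn + ewn + ea_normalized) / 4.0


# ---------------------------------------------------------------------------
# Fitted parameters
# ---------------------------------------------------------------------------

@dataclass
class ErrorModelParams:
    """Calibrated empirical error model.

    ``reference_errors``, ``weight_factors`` and ``correction_factors`` are
    nested dicts ``modality -> factor -> value``.  ``levels`` maps each
    factor to its ordered non-reference level keys (surface ids / weights),
    with the designated hold-outs in ``holdouts``.  ``per_level_weight_factors``
    keeps the individual per-level fits; predictions default to the averaged
    Wf but the per-level values are exposed for condition-specific use.
    ``normalization`` rescales the accelerometer error (g) to EEG units (uV).
    """

    reference_errors: dict
    weight_factors: dict
    correction_factors: dict
    per_level_weight_factors: dict
    friction_table: dict
    subject_weights: list
    wheelchair_weights: list
    reference_surface: str
    reference_friction: float
    reference_subject_weight: float
    reference_wheelchair_weight: float
    holdouts: dict
    normalization: float = 1.0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorModelParams":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "ErrorModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _mean_condition_error(
    motion_epochs: list[Epoch], ref_epochs: list[Epoch], modality: str
) -> float:
    """Mean windowed error of a motion condition against the reference.

    Motion epoch i is paired with reference epoch i mod n_ref (the sessions
    are not sample-synchronized, so pairing is by position only).
    """
    vals = [
        measure_window_error(ep, ref_epochs[i % len(ref_epochs)], modality).value
        for i, ep in enumerate(motion_epochs)
    ]
    return float(np.mean(vals))


def _level_ratio(factor: str, ref_level: float, level: float) -> float:
    # all three factors use reference/level ratios (mu1/mun, W1/Wn, U1/Un)
    return ref_level / level


def calibrate(
    reference_rec: Recording,
    motion_recs: Sequence[Recording],
    holdouts: Mapping[str, Sequence] | None = None,
) -> ErrorModelParams:
    """Fit the empirical error model from a one-factor-at-a-time design.

    ``reference_rec`` is the stationary baseline session; its metadata names
    the baseline surface, subject weight and wheelchair weight.  Motion
    recordings whose metadata matches the baseline on all three factors give
    the reference errors E_1; recordings varying exactly one factor give the
    per-level errors used to fit that factor's weight factor.  Hold-out
    levels (default: the last two levels of each factor, in order of first
    appearance) supply the correction factors.
    """
    if not reference_rec.meta.is_reference:
        raise CalibrationError("reference recording must have is_reference=True")
    if not motion_recs:
        raise CalibrationError("no motion recordings supplied")

    ref_epochs = segment_by_cues(reference_rec)
    if not ref_epochs:
        raise CalibrationError("reference recording has no epochs")

    base = reference_rec.meta
    b_surface, b_w, b_u = base.surface_id, base.subject_weight, base.wheelchair_weight

    friction_table: dict[str, float] = {b_surface: base.friction}
    subject_weights: list[float] = [b_w]
    wheelchair_weights: list[float] = [b_u]

    # group recordings: baseline cells and one-factor-varying cells
    baseline_recs: list[Recording] = []
    by_level: dict[str, dict] = {f: {} for f in FACTORS}  # factor -> level key -> [recs]
    level_ratio: dict[str, dict] = {f: {} for f in FACTORS}
    for rec in motion_recs:
        m = rec.meta
        if m.is_reference:
            continue
        at_surface = m.surface_id == b_surface
        at_subject = m.subject_weight == b_w
        at_chair = m.wheelchair_weight == b_u
        friction_table.setdefault(m.surface_id, m.friction)
        if m.subject_weight not in subject_weights:
            subject_weights.append(m.subject_weight)
        if m.wheelchair_weight not in wheelchair_weights:
            wheelchair_weights.append(m.wheelchair_weight)
        if at_surface and at_subject and at_chair:
            baseline_recs.append(rec)
            continue
        if not at_surface and at_subject and at_chair:
            by_level["surface"].setdefault(m.surface_id, []).append(rec)
            level_ratio["surface"][m.surface_id] = base.friction / m.friction
        elif at_surface and not at_subject and at_chair:
            by_level["subject"].setdefault(m.subject_weight, []).append(rec)
            level_ratio["subject"][m.subject_weight] = b_w / m.subject_weight
        elif at_surface and at_subject and not at_chair:
            by_level["wheelchair"].setdefault(m.wheelchair_weight, []).append(rec)
            level_ratio["wheelchair"][m.wheelchair_weight] = b_u / m.wheelchair_weight
        # cells varying >1 factor are not usable for one-factor fits

    if not baseline_recs:
        raise CalibrationError(
            "missing baseline motion recordings (all factors at reference levels)"
        )

    # hold-out designation: last two levels per factor, in appearance order
    holdouts_resolved: dict[str, list] = {}
    for factor in FACTORS:
        levels = list(by_level[factor])
        if len(levels) < 2:
            raise CalibrationError(
                f"factor {factor!r} has {len(levels)} non-reference level(s); "
                "at least 2 are required"
            )
        if holdouts is not None and factor in holdouts:
            ho = list(holdouts[factor])
        else:
            ho = levels[-2:]
        missing = [h for h in ho if h not in levels]
        if missing:
            raise CalibrationError(
                f"hold-out level(s) {missing} absent for factor {factor!r}"
            )
        holdouts_resolved[factor] = ho

    def epochs_of(recs: list[Recording]) -> list[Epoch]:
        out: list[Epoch] = []
        for r in recs:
            out.extend(segment_by_cues(r))
        return out

    base_epochs = epochs_of(baseline_recs)

    reference_errors: dict = {m: {} for m in MODALITIES}
    weight_factors: dict = {m: {} for m in MODALITIES}
    correction_factors: dict = {m: {} for m in MODALITIES}
    per_level_wf: dict = {m: {} for m in MODALITIES}

    for modality in MODALITIES:
        e1 = _mean_condition_error(base_epochs, ref_epochs, modality)
        if e1 == 0.0:
            raise CalibrationError(
                f"zero reference error for modality {modality!r}: cannot calibrate"
            )
        for factor in FACTORS:
            reference_errors[modality][factor] = e1
            measured: dict = {}
            for level, recs in by_level[factor].items():
                measured[level] = _mean_condition_error(
                    epochs_of(recs), ref_epochs, modality
                )
            wfs = {
                level: fit_weight_factor(measured[level], e1, level_ratio[factor][level])
                for level in by_level[factor]
            }
            wf = average_weight_factors(list(wfs.values()))
            predicted_holdout = {
                level: predict_factor_error(e1, level_ratio[factor][level], wf, 0.0)
                for level in holdouts_resolved[factor]
            }
            measured_holdout = {level: measured[level] for level in holdouts_resolved[factor]}
            cf = fit_correction_factor(measured_holdout, predicted_holdout)
            weight_factors[modality][factor] = wf
            correction_factors[modality][factor] = cf
            per_level_wf[modality][factor] = {str(k): v for k, v in wfs.items()}

    # map accelerometer error (g) onto the EEG error scale (uV)
    ref_accel = combine_axes(
        reference_errors["accel_x"]["surface"],
        reference_errors["accel_y"]["surface"],
        reference_errors["accel_z"]["surface"],
    )
    ref_eeg = reference_errors["eeg_avg"]["surface"]
    normalization = ref_eeg / ref_accel if ref_accel != 0.0 else 1.0

    return ErrorModelParams(
        reference_errors=reference_errors,
        weight_factors=weight_factors,
        correction_factors=correction_factors,
        per_level_weight_factors=per_level_wf,
        friction_table=friction_table,
        subject_weights=subject_weights,
        wheelchair_weights=wheelchair_weights,
        reference_surface=b_surface,
        reference_friction=base.friction,
        reference_subject_weight=b_w,
        reference_wheelchair_weight=b_u,
        holdouts={f: [str(h) for h in hs] for f, hs in holdouts_resolved.items()},
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# Prediction and correction
# ---------------------------------------------------------------------------

def _factor_ratios(params: ErrorModelParams, meta) -> dict[str, float]:
    return {
        "surface": params.reference_friction / meta.friction,
        "subject": params.reference_subject_weight / meta.subject_weight,
        "wheelchair": params.reference_wheelchair_weight / meta.wheelchair_weight,
    }


def predict_condition_error(params: ErrorModelParams, meta) -> dict:
    """Predict the total EEG-scale error for a motion condition.

    Returns a breakdown dict with per-factor EEG errors (``eeg_surface``,
    ``eeg_subject``, ``eeg_wheelchair``), the combined accelerometer errors
    per factor, their average ``ea`` (g) and EEG-normalized value, and the
    final ``total`` (uV).
    """
    ratios = _factor_ratios(params, meta)

    def pred(modality: str, factor: str) -> float:
        return predict_factor_error(
            params.reference_errors[modality][factor],
            ratios[factor],
            params.weight_factors[modality][factor],
            params.correction_factors[modality][factor],
        )

    out: dict = {}
    accel_by_factor = {}
    for factor in FACTORS:
        out[f"eeg_{factor}"] = pred("eeg_avg", factor)
        accel_by_factor[factor] = combine_axes(
            pred("accel_x", factor), pred("accel_y", factor), pred("accel_z", factor)
        )
        out[f"accel_{factor}"] = accel_by_factor[factor]
    ea = accel_error(
        accel_by_factor["surface"], accel_by_factor["subject"], accel_by_factor["wheelchair"]
    )
    out["ea"] = ea
    out["ea_normalized"] = ea * params.normalization
    out["total"] = total_error(
        out["eeg_surface"], out["eeg_subject"], out["eeg_wheelchair"], out["ea_normalized"]
    )
    return out


def apply_correction(avg: np.ndarray, e_total: float) -> np.ndarray:
    """Remove the predicted error from the averaged EEG series by RMS
    shrinkage.

    The series is scaled so its RMS drops by ``e_total``; a non-positive
    error leaves the series unchanged, and an error at or above the series
    RMS floors the output at zero.
    """
    avg = np.asarray(avg, dtype=float)
    if not np.isfinite(e_total):
        raise ValueError("e_total must be finite")
    if e_total <= 0.0:
        return avg.copy()
    rms = float(np.sqrt(np.mean(avg**2))) if avg.size else 0.0
    if rms <= e_total:
        return np.zeros_like(avg)
    return avg * ((rms - e_total) / rms)
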