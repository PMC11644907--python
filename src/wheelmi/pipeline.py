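"""End-to-end pipeline: epochs -> reshape -> (correction) -> features -> CNN.

``run_pipeline`` executes the full flow on a set of recordings: segment the
cue epochs, average the 8 channels, optionally calibrate the empirical error
model on the stationary reference and shrink each epoch's amplitude by its
condition's predicted error, re-expand to 8 channels, extract the per-epoch
feature grids, split 80:20 stratified by class, train the CNN and report
metrics.  ``run_validation_case`` repeats this per condition level (per
surface or per wheelchair), with or without the correction, mirroring the
four validation scenarios.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .classifier import Metrics, ModelConfig, TrainedClassifier, build_model, evaluate, train
from .error_model import (
    ErrorModelParams,
    apply_correction,
    calibrate,
    predict_condition_error,
)
from .features import FeatureMatrix, build_feature_matrix
from .io_formats import LABELS, Epoch, Recording, segment_by_cues
from .reshape import reshape1, reshape2

logger = logging.getLogger("wheelmi.pipeline")

__all__ = ["PipelineConfig", "CaseReport", "run_pipeline", "run_validation_case"]

CASE_AXES = {"a": "surface", "b": "wheelchair", "c": "surface", "d": "wheelchair"}
CASE_CORRECTION = {"a": False, "b": False, "c": True, "d": True}
CASE_MIN_LEVELS = {"surface": 5, "wheelchair": 3}


@dataclass(frozen=True)
class PipelineConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    n_subwindows: int = 8
    overlap_fraction: float = 0.5
    test_size: float = 0.2
    include_labels: tuple[str, ...] = LABELS

    def snapshot(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.snapshot(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _split_reference(recordings: Sequence[Recording]):
    refs = [r for r in recordings if r.meta.is_reference]
    motion = [r for r in recordings if not r.meta.is_reference]
    return refs, motion


def correct_epoch(epoch: Epoch, params: ErrorModelParams, e_total: float | None = None) -> Epoch:
    """Apply the empirical correction to one epoch's EEG (accel unchanged)."""
    if e_total is None:
        e_total = predict_condition_error(params, epoch.meta)["total"]
    avg, weights = reshape1(epoch.eeg)
    corrected = apply_correction(avg, e_total)
    return Epoch(
        eeg=reshape2(corrected, weights),
        accel=epoch.accel,
        label=epoch.label,
        fs=epoch.fs,
        meta=epoch.meta,
    )


def _feature_matrices(
    epochs: Sequence[Epoch], cfg: PipelineConfig, source: str
) -> tuple[np.ndarray, np.ndarray]:
    grids, labels = [], []
    for ep in epochs:
        fm = build_feature_matrix(
            ep, cfg.n_subwindows, cfg.overlap_fraction, stats=None, source=source
        )
        grids.append(fm.grid)
        labels.append(ep.label)
    return np.stack(grids), np.asarray(labels)


def run_pipeline(
    recordings: Sequence[Recording],
    use_empirical_model: bool,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    params: ErrorModelParams | None = None,
) -> tuple[TrainedClassifier, Metrics, dict]:
    """Run the full classification flow; returns (classifier, metrics, report).

    When ``use_empirical_model`` is set, the error model is calibrated on the
    supplied reference recording (unless pre-fitted ``params`` are given) and
    every motion epoch's averaged EEG is shrunk by its condition's predicted
    total error before feature extraction.  Reference recordings never enter
    the train/test pool.  Everything is reproducible from ``seed``.
    """
    if len(recordings) == 0:
        raise ValueError("empty recording list")
    cfg = cfg or PipelineConfig()
    refs, motion = _split_reference(recordings)
    if not motion:
        raise ValueError("no motion recordings to classify")
    if use_empirical_model and params is None:
        if not refs:
            raise ValueError("empirical correction requested but no reference recording given")
        params = calibrate(refs[0], motion)
    logger.info(
        "pipeline: %d recordings, correction=%s, seed=%d, config=%s",
        len(recordings), use_empirical_model, seed, cfg.config_hash(),
    )

    epochs: list[Epoch] = []
    e_cache: dict = {}
    for rec in motion:
        for ep in segment_by_cues(rec, cfg.include_labels):
            if use_empirical_model:
                if ep.meta not in e_cache:
                    e_cache[ep.meta] = predict_condition_error(params, ep.meta)["total"]
                ep = correct_epoch(ep, params, e_cache[ep.meta])
            epochs.append(ep)

    source = "corrected_avg" if use_empirical_model else "raw_avg"
    X, y = _feature_matrices(epochs, cfg, source)

    idx = np.arange(len(y))
    tr, te = train_test_split(
        idx, test_size=cfg.test_size, stratify=y, random_state=seed, shuffle=True
    )
    # standardize features with training-set statistics only
    rows = X[tr].reshape(-1, X.shape[-1])
    mu, sigma = rows.mean(axis=0), rows.std(axis=0)
    sigma = np.where(sigma == 0.0, 1.0, sigma)
    Xs = (X - mu) / sigma

    model_cfg = replace(cfg.model, seed=seed)
    model = build_model(model_cfg, Xs.shape[1:3])
    clf = train(model, Xs[tr][..., None], y[tr], model_cfg)
    clf.feature_stats = (mu, sigma)
    metrics = evaluate(clf, Xs[te][..., None], y[te])
    fragment = {
        "use_empirical_model": use_empirical_model,
        "seed": seed,
        "split": {"train": int(len(tr)), "test": int(len(te)), "test_size": cfg.test_size},
        "n_epochs_total": int(len(y)),
        "config_hash": cfg.config_hash(),
        "metrics": metrics.as_dict(),
    }
    return clf, metrics, fragment


@dataclass
class CaseReport:
    """Per-condition metrics for one validation scenario.

    Cases 'a'/'b' classify uncorrected data across 5 surfaces / 3
    wheelchairs; 'c'/'d' repeat them with the empirical correction applied.
    """

    case_id: str
    correction: bool
    per_condition: dict
    config: dict
    seed: int

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "correction": self.correction,
            "per_condition": self.per_condition,
            "config": self.config,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.as_dict(), indent=1, sort_keys=True, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_validation_case(
    case_id: str,
    recordings: Sequence[Recording],
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> CaseReport:
    """One validation scenario: per-level metrics along the case's axis.

    The dataset must cover the case's condition axis (5 surfaces for a/c,
    3 wheelchairs for b/d) for a single subject and a single value of the
    other vehicle factor (the baseline levels).  For the corrected cases the
    error model is calibrated once on the full dataset, then applied per
    level.
    """
    if case_id not in CASE_AXES:
        raise ValueError(f"case_id must be one of {sorted(CASE_AXES)}, got {case_id!r}")
    cfg = cfg or PipelineConfig()
    axis = CASE_AXES[case_id]
    correction = CASE_CORRECTION[case_id]
    refs, motion = _split_reference(recordings)
    if not motion:
        raise ValueError("no motion recordings in dataset")

    if refs:
        base = refs[0].meta
        b_subject, b_chair, b_surface = (
            base.subject_weight, base.wheelchair_weight, base.surface_id,
        )
    else:
        b_subject = motion[0].meta.subject_weight
        b_chair = motion[0].meta.wheelchair_weight
        b_surface = motion[0].meta.surface_id

    if axis == "surface":
        pool = [
            r for r in motion
            if r.meta.subject_weight == b_subject and r.meta.wheelchair_weight == b_chair
        ]
        levels: dict = {}
        for r in pool:
            levels.setdefault(r.meta.surface_id, []).append(r)
    else:
        pool = [
            r for r in motion
            if r.meta.subject_weight == b_subject and r.meta.surface_id == b_surface
        ]
        levels = {}
        for r in pool:
            levels.setdefault(r.meta.wheelchair_id, []).append(r)
    if len(levels) < CASE_MIN_LEVELS[axis]:
        raise ValueError(
            f"case {case_id!r} needs {CASE_MIN_LEVELS[axis]} {axis} levels, "
            f"dataset provides {len(levels)}"
        )

    params = None
    if correction:
        if not refs:
            raise ValueError("corrected case requires a reference recording")
        params = calibrate(refs[0], motion)

    per_condition = {}
    for level in sorted(levels):
        _, metrics, frag = run_pipeline(
            levels[level], correction, cfg, seed=seed, params=params
        )
        per_condition[str(level)] = frag["metrics"]
    return CaseReport(
        case_id=case_id,
        correction=correction,
        per_condition=per_condition,
        config=cfg.snapshot(),
        seed=seed,
    )
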