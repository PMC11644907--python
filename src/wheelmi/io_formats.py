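"""Recording containers and file I/O for synchronized EEG + accelerometer data.

A recording is an 8-channel scalp EEG stream (microvolts) with a 3-axis
accelerometer stream (g) sampled on the same clock, plus per-session metadata
(subject weight, wheelchair weight, terrain friction) and the RELAX/LEFT/RIGHT
cue schedule shown to the subject.  Files are plain delimited text in the
style of OpenBCI GUI exports: a ``%``-commented header, one row per sample
with ``[sample_index, 8 x EEG, ax, ay, az]`` columns, and a JSON sidecar
carrying metadata and the cue schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MONTAGE",
    "LABELS",
    "FileDialect",
    "FormatError",
    "MontageError",
    "BoundsError",
    "RecordingMeta",
    "CueEntry",
    "CueSchedule",
    "Recording",
    "Epoch",
    "read_recording",
    "write_recording",
    "segment_by_cues",
]

#: Electrode montage, in file column order.
DEFAULT_MONTAGE = ("Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4")

#: Canonical cue labels.
LABELS = ("RELAX", "LEFT", "RIGHT")

ACCEL_AXES = ("ax", "ay", "az")


class FormatError(ValueError):
    """Malformed recording file (missing column, non-numeric cell, ...)."""


class MontageError(FormatError):
    """Channel layout does not match the configured montage."""


class BoundsError(ValueError):
    """A cue window falls outside the recorded sample range."""


@dataclass(frozen=True)
class FileDialect:
    """Delimited-text dialect for recording files.

    ``eeg_columns`` / ``accel_columns`` are zero-based column indices in the
    data file; the default layout is ``[sample_index, EEG x 8, ax, ay, az]``.
    """

    delimiter: str = ","
    comment: str = "%"
    index_column: int = 0
    eeg_columns: tuple[int, ...] = tuple(range(1, 9))
    accel_columns: tuple[int, ...] = (9, 10, 11)


@dataclass(frozen=True)
class RecordingMeta:
    """Per-session motion-condition metadata.

    subject_weight (W) and wheelchair_weight (U) are in kg; friction is the
    dimensionless tire-surface coefficient (mu) of the terrain surface_id.
    ``is_reference`` marks the stationary, artifact-minimized baseline
    session used to calibrate the empirical error model.
    """

    subject_weight: float
    wheelchair_weight: float
    surface_id: str
    friction: float
    wheelchair_id: str = "u1"
    is_reference: bool = False
    trial: int = 0

    def __post_init__(self) -> None:
        if self.subject_weight <= 0:
            raise ValueError("subject_weight must be > 0")
        if self.wheelchair_weight <= 0:
            raise ValueError("wheelchair_weight must be > 0")
        if self.friction <= 0:
            raise ValueError("friction must be > 0")


@dataclass(frozen=True)
class CueEntry:
    label: str
    start_s: float
    duration_s: float = 5.0


@dataclass(frozen=True)
class CueSchedule:
    """Time-ordered, non-overlapping cue prompts (default 5 s each)."""

    entries: tuple[CueEntry, ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for e in self.entries:
            if e.duration_s <= 0:
                raise ValueError(f"cue {e.label!r} has non-positive duration")
            if e.start_s < prev_end - 1e-12:
                raise ValueError("cue entries overlap or are out of order")
            prev_end = e.start_s + e.duration_s

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def interleaved(cls, n_trials_per_class: int, duration_s: float = 5.0) -> "CueSchedule":
        """RELAX, LEFT, RELAX, RIGHT, ... protocol: every motor cue is
        preceded by a RELAX cue.  Yields 2*n RELAX and n LEFT / n RIGHT."""
        entries = []
        t = 0.0
        for _ in range(n_trials_per_class):
            for label in ("RELAX", "LEFT", "RELAX", "RIGHT"):
                entries.append(CueEntry(label, t, duration_s))
                t += duration_s
        return cls(tuple(entries))

    @classmethod
    def relax_only(cls, n: int, duration_s: float = 5.0) -> "CueSchedule":
        """A RELAX-only schedule, used for artifact calibration sessions."""
        return cls(tuple(CueEntry("RELAX", i * duration_s, duration_s) for i in range(n)))


@dataclass
class Recording:
    """Synchronized 8-channel EEG (uV) + 3-axis accelerometer (g) series."""

    eeg: np.ndarray  # (8, n_samples), microvolts
    accel: np.ndarray  # (3, n_samples), g
    fs: float
    cues: CueSchedule
    meta: RecordingMeta
    channel_names: tuple[str, ...] = DEFAULT_MONTAGE

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.eeg.ndim != 2 or self.eeg.shape[0] != 8:
            raise MontageError(f"eeg must be 8 x n, got shape {self.eeg.shape}")
        if self.accel.ndim != 2 or self.accel.shape[0] != 3:
            raise FormatError(f"accel must be 3 x n, got shape {self.accel.shape}")
        if self.eeg.shape[1] != self.accel.shape[1]:
            raise FormatError("eeg and accel must share the sample count")
        if len(self.channel_names) != 8:
            raise MontageError("channel_names must list exactly 8 electrodes")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.eeg.size and not np.isfinite(self.eeg).all():
            raise ValueError("eeg contains non-finite samples")
        if self.accel.size and not np.isfinite(self.accel).all():
            raise ValueError("accel contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """One cue-aligned window (default 5 s): the unit of error measurement,
    feature extraction, and classification."""

    eeg: np.ndarray  # (8, n)
    accel: np.ndarray  # (3, n)
    label: str
    fs: float
    meta: RecordingMeta

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _meta_to_dict(rec: Recording) -> dict:
    m = rec.meta
    return {
        "subject_weight": m.subject_weight,
        "wheelchair_weight": m.wheelchair_weight,
        "surface_id": m.surface_id,
        "friction": m.friction,
        "wheelchair_id": m.wheelchair_id,
        "is_reference": m.is_reference,
        "trial": m.trial,
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "cues": [
            {"label": e.label, "start_s": e.start_s, "duration_s": e.duration_s}
            for e in rec.cues
        ],
    }


def _meta_from_dict(d: dict) -> tuple[RecordingMeta, float, CueSchedule, tuple[str, ...]]:
    meta = RecordingMeta(
        subject_weight=d["subject_weight"],
        wheelchair_weight=d["wheelchair_weight"],
        surface_id=d["surface_id"],
        friction=d["friction"],
        wheelchair_id=d.get("wheelchair_id", "u1"),
        is_reference=d.get("is_reference", False),
        trial=d.get("trial", 0),
    )
    cues = CueSchedule(
        tuple(CueEntry(c["label"], c["start_s"], c.get("duration_s", 5.0)) for c in d["cues"])
    )
    names = tuple(d.get("channel_names", DEFAULT_MONTAGE))
    return meta, float(d["fs"]), cues, names


def write_recording(rec: Recording, path: str | Path, dialect: FileDialect | None = None) -> None:
    """Write ``rec`` as delimited text plus a ``<name>.meta.json`` sidecar.

    The data file is re-readable by :func:`read_recording` with equal content
    (within float text round-trip precision).
    """
    dialect = dialect or FileDialect()
    path = Path(path)
    n = rec.n_samples
    data = np.empty((n, 12))
    data[:, dialect.index_column] = np.arange(n)
    data[:, list(dialect.eeg_columns)] = rec.eeg.T
    data[:, list(dialect.accel_columns)] = rec.accel.T
    header = (
        f"{dialect.comment} 8-channel EEG (uV) + 3-axis accelerometer (g)\n"
        f"{dialect.comment} columns: sample_index,"
        + ",".join(rec.channel_names) + "," + ",".join(ACCEL_AXES) + "\n"
        f"{dialect.comment} fs = {rec.fs} Hz\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.17g", delimiter=dialect.delimiter)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(_meta_to_dict(rec), fh, indent=1)


def read_recording(path: str | Path, dialect: FileDialect | None = None) -> Recording:
    """Read a delimited-text recording written by :func:`write_recording`.

    Lines starting with the dialect's comment character are skipped.  Raises
    :class:`FormatError` naming the offending column or line on malformed
    input, and :class:`MontageError` when fewer than 8 EEG columns resolve.
    """
    dialect = dialect or FileDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    with open(sidecar) as fh:
        meta, fs, cues, names = _meta_from_dict(json.load(fh))

    needed = max((dialect.index_column, *dialect.eeg_columns, *dialect.accel_columns)) + 1
    if len(dialect.eeg_columns) < 8:
        raise MontageError(
            f"dialect maps only {len(dialect.eeg_columns)} EEG columns; 8 required"
        )
    try:
        df = pd.read_csv(
            path,
            sep=dialect.delimiter,
            comment=dialect.comment,
            header=None,
            dtype=float,
        )
    except ValueError:
        _locate_bad_cell(path, dialect)  # raises FormatError with line number
        raise
    if len(df) and df.shape[1] < needed:
        missing = [c for c in (*dialect.eeg_columns, *dialect.accel_columns) if c >= df.shape[1]]
        raise FormatError(f"file has {df.shape[1]} columns; missing column index {missing[0]}")
    if len(df) == 0:
        eeg = np.empty((8, 0))
        accel = np.empty((3, 0))
    else:
        arr = df.to_numpy(dtype=float)
        eeg = arr[:, list(dialect.eeg_columns)].T
        accel = arr[:, list(dialect.accel_columns)].T
    return Recording(eeg=eeg, accel=accel, fs=fs, cues=cues, meta=meta, channel_names=names)


def _locate_bad_cell(path: Path, dialect: FileDialect) -> None:
    """Scan the file to report the first non-numeric cell with its line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(dialect.comment):
                continue
            for cell in s.split(dialect.delimiter):
                try:
                    float(cell)
                except ValueError:
                    raise FormatError(
                        f"non-numeric cell {cell!r} at line {lineno} of {path}"
                    ) from None


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_by_cues(
    rec: Recording, include_labels: Iterable[str] | None = None
) -> list[Epoch]:
    """Cut ``rec`` into one cue-aligned :class:`Epoch` per schedule entry.

    Epochs start exactly at cue onset with no padding; an entry whose window
    extends past the end of the recording raises :class:`BoundsError` (partial
    epochs are rejected, not truncated).
    """
    include = set(include_labels) if include_labels is not None else set(LABELS)
    epochs: list[Epoch] = []
    for i, e in enumerate(rec.cues):
        start = int(round(e.start_s * rec.fs))
        n = int(round(e.duration_s * rec.fs))
        if start + n > rec.n_samples:
            raise BoundsError(
                f"cue entry {i} ({e.label} @ {e.start_s}s) extends past the "
                f"recording end ({rec.duration_s:.3f}s)"
            )
        if e.label not in include:
            continue
        epochs.append(
            Epoch(
                eeg=rec.eeg[:, start : start + n],
                accel=rec.accel[:, start : start + n],
                label=e.label,
                fs=rec.fs,
                meta=rec.meta,
            )
        )
    return epochs
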