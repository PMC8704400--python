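"""Data model, sensor-log I/O and fixed-window segmentation for wrist acceleration.

A smartwatch accelerometer stream is a sequence of timestamped 3-axis samples
in units of G (1 G = 9.8 m/s^2, the convention of watch motion frameworks:
a device lying screen-up reads -1 G on its z axis).  A :class:`Recording` holds
one labeled bout of a single trampoline motion for one (subject, set); the
classifier never sees whole recordings, only fixed-length :class:`Window` s cut
from them by :func:`segment`.

Windowing is index based: with the nominal 100 Hz rate, the default 64-sample
window covers 0.64 s of movement.  Timestamps are used only for validation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("trampohar")

#: conversion constant between the device unit (G) and SI acceleration.
G_TO_MS2 = 9.8

SENSOR_LOG_COLUMNS = ("t", "x", "y", "z")


class MotionLabel(Enum):
    """The six trampoline motions, in fixed protocol order.

    This ordering (ST, WL, MR, TJ, LJ, RJ) is used everywhere a class axis
    appears: confusion matrices, model outputs, rendered tables.
    """

    ST = "stand"
    WL = "walk"
    MR = "march"
    TJ = "two-leg jump"
    LJ = "one-leg jump (left)"
    RJ = "one-leg jump (right)"

    @property
    def code(self) -> str:
        return self.name

    @property
    def display_name(self) -> str:
        return self.value

    @property
    def index(self) -> int:
        return LABEL_ORDER.index(self)

    @classmethod
    def from_code(cls, code: str) -> "MotionLabel":
        try:
            return cls[code.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown motion label {code!r}; expected one of "
                f"{[l.name for l in cls]}"
            ) from None


#: canonical class order for all matrices and model outputs
LABEL_ORDER: tuple[MotionLabel, ...] = (
    MotionLabel.ST,
    MotionLabel.WL,
    MotionLabel.MR,
    MotionLabel.TJ,
    MotionLabel.LJ,
    MotionLabel.RJ,
)

N_CLASSES = len(LABEL_ORDER)


class SensorLogError(ValueError):
    """Raised when a sensor-log CSV violates the format contract."""


@dataclass
class Recording:
    """One labeled 3-axis acceleration bout for a (subject, set, motion).

    ``t`` is in seconds and strictly increasing; ``values`` is an (N, 3) float
    array in G with axis order (x, y, z).  The study protocol records 10 s
    bouts at a nominal 100 Hz, but arbitrary durations are accepted.
    """

    subject_id: str
    set_index: int
    label: MotionLabel
    sample_rate_hz: float
    t: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise SensorLogError(
                f"expected an (N, 3) axis array, got shape {self.values.shape}"
            )
        if self.t.shape != (self.values.shape[0],):
            raise SensorLogError("timestamp and sample counts disagree")
        if self.sample_rate_hz <= 0:
            raise SensorLogError("sample_rate_hz must be positive")
        if not np.all(np.isfinite(self.values)) or not np.all(np.isfinite(self.t)):
            raise SensorLogError("non-finite sample values")
        bad = np.flatnonzero(np.diff(self.t) <= 0)
        if bad.size:
            raise SensorLogError(
                f"timestamps not strictly increasing at sample {bad[0] + 1}"
            )

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return float(len(self) / self.sample_rate_hz)


@dataclass(frozen=True)
class WindowingConfig:
    """Fixed-window segmentation parameters (samples, not seconds)."""

    window_size: int = 64
    stride: int = 64

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.stride < 1:
            raise ValueError("window_size and stride must be >= 1")


@dataclass
class Window:
    """A (window_size, 3) slice of a recording with its provenance."""

    values: np.ndarray
    label: MotionLabel
    subject_id: str
    set_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError(f"expected (W, 3) values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window contains non-finite values")


@dataclass(frozen=True)
class ManifestEntry:
    file_path: str
    subject_id: str
    set_index: int
    label: MotionLabel
    sample_rate_hz: float = 100.0


@dataclass
class DatasetManifest:
    """Maps sensor-log files to (subject, set, label, rate) metadata."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        paths = [e.file_path for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest file paths must be unique")

    def __iter__(self) -> Iterator[ManifestEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.subject_id, None)
        return list(seen)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["file_path", "subject_id", "set_index", "label", "sample_rate_hz"])
            for e in self.entries:
                w.writerow(
                    [e.file_path, e.subject_id, e.set_index, e.label.code, repr(e.sample_rate_hz)]
                )

    @classmethod
    def read(cls, path: str | Path) -> "DatasetManifest":
        df = pd.read_csv(path, dtype={"subject_id": str})
        required = {"file_path", "subject_id", "set_index", "label", "sample_rate_hz"}
        missing = required - set(df.columns)
        if missing:
            raise SensorLogError(f"manifest {path} missing columns {sorted(missing)}")
        entries = [
            ManifestEntry(
                file_path=str(r.file_path),
                subject_id=str(r.subject_id),
                set_index=int(r.set_index),
                label=MotionLabel.from_code(str(r.label)),
                sample_rate_hz=float(r.sample_rate_hz),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(entries=entries)


def read_recording(path: str | Path, entry: ManifestEntry) -> Recording:
    """Read one sensor-log CSV (header ``t,x,y,z``) as a :class:`Recording`.

    Raises :class:`SensorLogError` naming the first offending CSV line for
    missing columns, non-numeric rows, or non-increasing timestamps.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SENSOR_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise SensorLogError(f"{path}: missing columns {sorted(missing)}")
    data = df.loc[:, list(SENSOR_LOG_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = np.flatnonzero(data.isna().any(axis=1).to_numpy())
    if bad.size:
        # +2: 1-based line numbering plus the header line
        raise SensorLogError(f"{path}: non-numeric or missing value on line {bad[0] + 2}")
    t = data["t"].to_numpy(dtype=float)
    nonmono = np.flatnonzero(np.diff(t) <= 0)
    if nonmono.size:
        raise SensorLogError(
            f"{path}: timestamps not strictly increasing on line {nonmono[0] + 3}"
        )
    return Recording(
        subject_id=entry.subject_id,
        set_index=entry.set_index,
        label=entry.label,
        sample_rate_hz=entry.sample_rate_hz,
        t=t,
        values=data[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as a ``t,x,y,z`` CSV (shortest round-trip floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SENSOR_LOG_COLUMNS)
        for t, (x, y, z) in zip(recording.t, recording.values):
            # repr() emits shortest round-trip floats, so read-back is exact
            w.writerow([repr(float(t)), repr(float(x)), repr(float(y)), repr(float(z))])


def load_dataset(
    manifest: DatasetManifest, root: str | Path | None = None
) -> list[Recording]:
    """Read every recording named by a manifest (paths relative to ``root``)."""
    root = Path(root) if root is not None else Path(".")
    return [read_recording(root / e.file_path, e) for e in manifest]


def segment(recording: Recording, config: WindowingConfig = WindowingConfig()) -> list[Window]:
    """Cut a recording into fixed windows; never spans recordings.

    Returns ``floor((N - window_size) / stride) + 1`` windows starting at
    offsets 0, stride, 2*stride, ...; an incomplete trailing window is dropped
    (no padding).  A recording shorter than one window yields an empty list
    with a logged warning rather than an error, to tolerate truncated sets.
    """
    n = len(recording)
    w, s = config.window_size, config.stride
    if n < w:
        logger.warning(
            "recording %s/set%d/%s has %d samples < window size %d; no windows",
            recording.subject_id, recording.set_index, recording.label.code, n, w,
        )
        return []
    starts = range(0, n - w + 1, s)
    return [
        Window(
            values=recording.values[i : i + w],
            label=recording.label,
            subject_id=recording.subject_id,
            set_index=recording.set_index,
        )
        for i in starts
    ]


def segment_all(
    recordings: Iterable[Recording], config: WindowingConfig = WindowingConfig()
) -> list[Window]:
    out: list[Window] = []
    for rec in recordings:
        out.extend(segment(rec, config))
    return out


def flatten_window(window: Window | np.ndarray) -> np.ndarray:
    """Lay the three axes out along one dimension: all x, then y, then z.

    A 64x3 window becomes a length-192 single-channel sequence, the input
    layout of the CNN.  :func:`unflatten_window` is its exact inverse.
    """
    values = window.values if isinstance(window, Window) else np.asarray(window)
    return values.T.reshape(-1)


def unflatten_window(flat: np.ndarray, window_size: int = 64) -> np.ndarray:
    flat = np.asarray(flat)
    if flat.size != 3 * window_size:
        raise ValueError(f"expected {3 * window_size} values, got {flat.size}")
    return flat.reshape(3, window_size).T


def windows_to_arrays(
    windows: Sequence[Window], layout: str = "flat"
) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into model-ready arrays.

    ``layout='flat'`` gives (n, 3W, 1) single-channel sequences (axis-major);
    ``layout='multichannel'`` gives (n, W, 3).  Labels are integer class
    indices in canonical order.
    """
    if not windows:
        raise ValueError("no windows to stack")
    y = np.array([w.label.index for w in windows], dtype=np.int64)
    if layout == "flat":
        x = np.stack([flatten_window(w)[:, None] for w in windows])
    elif layout == "multichannel":
        x = np.stack([w.values for w in windows])
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return x.astype(np.float32), y
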