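"""Hand-crafted time- and frequency-domain window features for the RF baseline.

Per 64-sample window the extractor computes, in a frozen order:

* time domain, per axis (16 x 3 = 48): mean, mean of absolute values,
  standard deviation, standard deviation of absolute values, minimum, maximum,
  root mean square, 1st quartile, median, 3rd quartile, interquartile range,
  initial value, final value, skewness, kurtosis (excess), zero-crossing rate;
* time domain, per axis pair (3 + 3): correlation coefficient and correlation
  of absolute values;
* per frame (1): intensity — the mean Euclidean norm of the 3-axis vector;
* frequency domain, per axis per band (9 x 3 x 4 = 108): maximum magnitude,
  frequency of the maximum, 2nd maximum, frequency of the 2nd maximum,
  standard deviation, 1st quartile, median, 3rd quartile, interquartile range
  of the one-sided FFT magnitudes (DC excluded) in the all-, low- (0-4.2 Hz),
  mid- (4.2-8.4 Hz) and high- (8.4-12.6 Hz) frequency bands;
* frequency domain, per axis pair per band (3 x 4 = 12): correlation of the
  in-band magnitudes.

Total 55 + 120 = 175.  Conventions (frozen by tests):

* moments are population moments; kurtosis is excess; both are imputed 0 when
  the variance is below 1e-12 (constant windows);
* the zero-crossing rate counts strict sign changes of the mean-removed
  signal, divided by (N - 1) — wrist signals carry a gravity offset that would
  otherwise zero the count;
* quartiles use linear interpolation; frequency-domain quartiles are
  quartiles of the in-band magnitude values;
* the "2nd maximum" is the largest magnitude bin not adjacent to the argmax
  bin (adjacent bins mostly report spectral leakage of the same peak); if no
  non-adjacent in-band bin exists, the value and its frequency are 0;
* correlations with a zero-variance argument are imputed 0; band edges are
  closed on the left, open on the right, so bands are disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .signal_core import Window

logger = logging.getLogger("trampohar")

AXES = ("x", "y", "z")
PAIRS = ((0, 1, "xy"), (0, 2, "xz"), (1, 2, "yz"))

N_TIME_FEATURES = 55
N_FREQ_FEATURES = 120
N_FEATURES = N_TIME_FEATURES + N_FREQ_FEATURES

_EPS_VAR = 1e-12


@dataclass(frozen=True)
class BandSpec:
    """A half-open frequency band [lo_hz, hi_hz); ``hi_hz=None`` means the
    full one-sided spectrum up to and including Nyquist."""

    name: str
    lo_hz: float
    hi_hz: float | None

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        m = freqs > 0  # DC excluded from every band
        if self.hi_hz is not None:
            m &= (freqs >= self.lo_hz) & (freqs < self.hi_hz)
        return m


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("all", 0.0, None),
    BandSpec("low", 0.0, 4.2),
    BandSpec("mid", 4.2, 8.4),
    BandSpec("high", 8.4, 12.6),
)


@dataclass(frozen=True)
class FeatureConfig:
    rate_hz: float = 100.0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS


@dataclass
class FeatureVector:
    """A fixed-length named feature vector; name order is identical for every
    window, so vectors stack directly into a model-ready table."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("values/names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with zero-variance inputs imputed as 0."""
    a = a - a.mean()
    b = b - b.mean()
    va, vb = float(a @ a), float(b @ b)
    if va < _EPS_VAR or vb < _EPS_VAR:
        return 0.0
    return float((a @ b) / np.sqrt(va * vb))


def _moments(v: np.ndarray) -> tuple[float, float]:
    """Population skewness and excess kurtosis, 0 on (near-)constant input."""
    c = v - v.mean()
    m2 = float(np.mean(c**2))
    if m2 < _EPS_VAR:
        return 0.0, 0.0
    m3 = float(np.mean(c**3))
    m4 = float(np.mean(c**4))
    return m3 / m2**1.5, m4 / m2**2 - 3.0


def _zcr(v: np.ndarray) -> float:
    s = v - v.mean()
    return float(np.count_nonzero(s[:-1] * s[1:] < 0) / (len(s) - 1))


def time_features(window: Window | np.ndarray) -> dict[str, float]:
    """The 55 time-domain features of one window (insertion-ordered)."""
    values = window.values if isinstance(window, Window) else np.asarray(window)
    out: dict[str, float] = {}
    for i, ax in enumerate(AXES):
        v = values[:, i]
        a = np.abs(v)
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        skew, kurt = _moments(v)
        out[f"time.{ax}.mean"] = float(v.mean())
        out[f"time.{ax}.abs_mean"] = float(a.mean())
        out[f"time.{ax}.std"] = float(v.std())
        out[f"time.{ax}.abs_std"] = float(a.std())
        out[f"time.{ax}.min"] = float(v.min())
        out[f"time.{ax}.max"] = float(v.max())
        out[f"time.{ax}.rms"] = float(np.sqrt(np.mean(v**2)))
        out[f"time.{ax}.q1"] = float(q1)
        out[f"time.{ax}.median"] = float(med)
        out[f"time.{ax}.q3"] = float(q3)
        out[f"time.{ax}.iqr"] = float(q3 - q1)
        out[f"time.{ax}.initial"] = float(v[0])
        out[f"time.{ax}.final"] = float(v[-1])
        out[f"time.{ax}.skewness"] = skew
        out[f"time.{ax}.kurtosis"] = kurt
        out[f"time.{ax}.zcr"] = _zcr(v)
    for i, j, pair in PAIRS:
        out[f"time.{pair}.corr"] = _corr(values[:, i], values[:, j])
    for i, j, pair in PAIRS:
        out[f"time.{pair}.abs_corr"] = _corr(np.abs(values[:, i]), np.abs(values[:, j]))
    out["time.frame.intensity"] = float(np.linalg.norm(values, axis=1).mean())
    return out


def _band_stats(mag: np.ndarray, freqs: np.ndarray, prefix: str) -> dict[str, float]:
    stats = ("max", "argmax_hz", "max2", "argmax2_hz", "std", "q1", "median", "q3", "iqr")
    if mag.size == 0:
        logger.warning("band %s has no FFT bins at this rate; features set to 0", prefix)
        return {f"{prefix}.{s}": 0.0 for s in stats}
    k = int(np.argmax(mag))
    max2 = 0.0
    arg2 = 0.0
    far = np.abs(np.arange(mag.size) - k) >= 2  # skip argmax and its neighbors
    if far.any():
        k2 = int(np.flatnonzero(far)[np.argmax(mag[far])])
        max2 = float(mag[k2])
        arg2 = float(freqs[k2])
    q1, med, q3 = np.quantile(mag, [0.25, 0.5, 0.75])
    return {
        f"{prefix}.max": float(mag[k]),
        f"{prefix}.argmax_hz": float(freqs[k]),
        f"{prefix}.max2": max2,
        f"{prefix}.argmax2_hz": arg2,
        f"{prefix}.std": float(mag.std()),
        f"{prefix}.q1": float(q1),
        f"{prefix}.median": float(med),
        f"{prefix}.q3": float(q3),
        f"{prefix}.iqr": float(q3 - q1),
    }


def frequency_features(
    window: Window | np.ndarray,
    rate_hz: float = 100.0,
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
) -> dict[str, float]:
    """The 120 frequency-domain features of one window (insertion-ordered)."""
    values = window.values if isinstance(window, Window) else np.asarray(window)
    n = values.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    mags = np.abs(np.fft.rfft(values, axis=0))  # (n//2+1, 3)
    out: dict[str, float] = {}
    for band in bands:
        m = band.mask(freqs)
        bf = freqs[m]
        for i, ax in enumerate(AXES):
            out.update(_band_stats(mags[m, i], bf, f"freq.{band.name}.{ax}"))
        for i, j, pair in PAIRS:
            out[f"freq.{band.name}.{pair}.corr"] = (
                _corr(mags[m, i], mags[m, j]) if m.sum() >= 2 else 0.0
            )
    return out


def extract(window: Window | np.ndarray, config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Full 175-entry feature vector of one window, names stable across calls."""
    feats = time_features(window)
    feats.update(frequency_features(window, config.rate_hz, config.bands))
    return FeatureVector(
        values=np.array(list(feats.values())), names=tuple(feats.keys())
    )


def feature_names(config: FeatureConfig = FeatureConfig()) -> tuple[str, ...]:
    probe = np.zeros((64, 3))
    return extract(probe, config).names


def extract_table(
    windows: Sequence[Window], config: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """Feature matrix for a window set, with subject/set/label metadata columns."""
    rows = [extract(w, config).values for w in windows]
    df = pd.DataFrame(np.vstack(rows), columns=list(feature_names(config)))
    df.insert(0, "subject_id", [w.subject_id for w in windows])
    df.insert(1, "set_index", [w.set_index for w in windows])
    df.insert(2, "label", [w.label.code for w in windows])
    return df
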