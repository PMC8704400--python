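"""Straight-from-definition oracles, independent of the package internals.

Everything here is computed with pure-Python loops and textbook formulas
(direct-summation DFT, central-moment definitions, interpolated quantiles) so
that agreement with the vectorized implementation is a genuine cross-check.
"""

from __future__ import annotations

import cmath
import math


def quantile(vals, q):
    s = sorted(vals)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    if lo == h:
        return s[int(h)]
    return s[lo] + (h - lo) * (s[lo + 1] - s[lo])


def corr(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    da = [v - ma for v in a]
    db = [v - mb for v in b]
    va = sum(v * v for v in da)
    vb = sum(v * v for v in db)
    if va < 1e-12 or vb < 1e-12:
        return 0.0
    return sum(x * y for x, y in zip(da, db)) / math.sqrt(va * vb)


def time_features_oracle(values) -> dict[str, float]:
    """values: (N, 3) nested sequence; returns the 55 time-domain features."""
    axes = list(zip(*[tuple(row) for row in values]))
    out: dict[str, float] = {}
    for name, v in zip("xyz", axes):
        n = len(v)
        a = [abs(u) for u in v]
        mean = sum(v) / n
        amean = sum(a) / n
        var = sum((u - mean) ** 2 for u in v) / n
        avar = sum((u - amean) ** 2 for u in a) / n
        q1, med, q3 = quantile(v, 0.25), quantile(v, 0.5), quantile(v, 0.75)
        if var < 1e-12:
            skew = kurt = 0.0
        else:
            m3 = sum((u - mean) ** 3 for u in v) / n
            m4 = sum((u - mean) ** 4 for u in v) / n
            skew = m3 / var**1.5
            kurt = m4 / var**2 - 3.0
        centered = [u - mean for u in v]
        zc = sum(
            1 for i in range(n - 1) if centered[i] * centered[i + 1] < 0
        ) / (n - 1)
        out[f"time.{name}.mean"] = mean
        out[f"time.{name}.abs_mean"] = amean
        out[f"time.{name}.std"] = math.sqrt(var)
        out[f"time.{name}.abs_std"] = math.sqrt(avar)
        out[f"time.{name}.min"] = min(v)
        out[f"time.{name}.max"] = max(v)
        out[f"time.{name}.rms"] = math.sqrt(sum(u * u for u in v) / n)
        out[f"time.{name}.q1"] = q1
        out[f"time.{name}.median"] = med
        out[f"time.{name}.q3"] = q3
        out[f"time.{name}.iqr"] = q3 - q1
        out[f"time.{name}.initial"] = v[0]
        out[f"time.{name}.final"] = v[-1]
        out[f"time.{name}.skewness"] = skew
        out[f"time.{name}.kurtosis"] = kurt
        out[f"time.{name}.zcr"] = zc
    pairs = ((0, 1, "xy"), (0, 2, "xz"), (1, 2, "yz"))
    for i, j, p in pairs:
        out[f"time.{p}.corr"] = corr(axes[i], axes[j])
    for i, j, p in pairs:
        out[f"time.{p}.abs_corr"] = corr(
            [abs(u) for u in axes[i]], [abs(u) for u in axes[j]]
        )
    out["time.frame.intensity"] = sum(
        math.sqrt(sum(u * u for u in row)) for row in values
    ) / len(values)
    return out


def dft_magnitudes(v):
    """One-sided DFT magnitudes by direct summation (bins 0..N//2)."""
    n = len(v)
    return [
        abs(sum(v[t] * cmath.exp(-2j * cmath.pi * k * t / n) for t in range(n)))
        for k in range(n // 2 + 1)
    ]


BAND_EDGES = {"all": None, "low": (0.0, 4.2), "mid": (4.2, 8.4), "high": (8.4, 12.6)}


def band_bins(n, rate, band):
    freqs = [k * rate / n for k in range(n // 2 + 1)]
    edges = BAND_EDGES[band]
    if edges is None:
        return [k for k, f in enumerate(freqs) if f > 0]
    lo, hi = edges
    return [k for k, f in enumerate(freqs) if f > 0 and lo <= f < hi]


def frequency_features_oracle(values, rate) -> dict[str, float]:
    """The 120 frequency-domain features via the direct-summation DFT."""
    axes = list(zip(*[tuple(row) for row in values]))
    n = len(values)
    mags = [dft_magnitudes(v) for v in axes]
    out: dict[str, float] = {}
    for band in ("all", "low", "mid", "high"):
        bins = band_bins(n, rate, band)
        for name, m in zip("xyz", mags):
            bm = [m[k] for k in bins]
            prefix = f"freq.{band}.{name}"
            if not bm:
                for s in ("max", "argmax_hz", "max2", "argmax2_hz", "std",
                          "q1", "median", "q3", "iqr"):
                    out[f"{prefix}.{s}"] = 0.0
                continue
            imax = max(range(len(bm)), key=lambda i: bm[i])
            far = [i for i in range(len(bm)) if abs(i - imax) >= 2]
            if far:
                i2 = max(far, key=lambda i: bm[i])
                max2, arg2 = bm[i2], bins[i2] * rate / n
            else:
                max2 = arg2 = 0.0
            mean = sum(bm) / len(bm)
            out[f"{prefix}.max"] = bm[imax]
            out[f"{prefix}.argmax_hz"] = bins[imax] * rate / n
            out[f"{prefix}.max2"] = max2
            out[f"{prefix}.argmax2_hz"] = arg2
            out[f"{prefix}.std"] = math.sqrt(
                sum((u - mean) ** 2 for u in bm) / len(bm)
            )
            out[f"{prefix}.q1"] = quantile(bm, 0.25)
            out[f"{prefix}.median"] = quantile(bm, 0.5)
            out[f"{prefix}.q3"] = quantile(bm, 0.75)
            out[f"{prefix}.iqr"] = quantile(bm, 0.75) - quantile(bm, 0.25)
        for i, j, p in ((0, 1, "xy"), (0, 2, "xz"), (1, 2, "yz")):
            bi = [mags[i][k] for k in bins]
            bj = [mags[j][k] for k in bins]
            out[f"freq.{band}.{p}.corr"] = corr(bi, bj) if len(bins) >= 2 else 0.0
    return out


def metrics_oracle(counts) -> dict:
    """Per-class precision/recall/F and accuracy from per-cell summation;
    rows = predicted, columns = correct."""
    k = len(counts)
    rows = [sum(counts[i][j] for j in range(k)) for i in range(k)]
    cols = [sum(counts[i][j] for i in range(k)) for j in range(k)]
    prec = [100.0 * counts[i][i] / rows[i] if rows[i] else 0.0 for i in range(k)]
    rec = [100.0 * counts[j][j] / cols[j] if cols[j] else 0.0 for j in range(k)]
    f = [
        2 * p * r / (p + r) if p + r > 0 else 0.0 for p, r in zip(prec, rec)
    ]
    total = sum(rows)
    acc = 100.0 * sum(counts[i][i] for i in range(k)) / total
    return {"precision": prec, "recall": rec, "f": f, "accuracy": acc}
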