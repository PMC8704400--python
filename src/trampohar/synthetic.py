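"""Synthetic multi-subject trampoline accelerometry.

The study data (wrist acceleration of subjects performing six motions on a
home trampoline) are not publicly deposited, so this module generates labeled
recordings with the statistical structure the classifiers exploit:

* a per-subject bounce carrier (1.2-2.6 Hz) with 2-3 harmonics and a
  half-frequency arm-swing component, so spectra look like real bouncing;
* class-specific structure — standing (ST) is noise about gravity; walking
  (WL) is a low-amplitude, lower-frequency quasi-periodic sway; marching (MR)
  alternates legs every cycle, which injects sub-harmonic (half-carrier)
  energy; the two-leg jump (TJ) has the largest vertical amplitude; the
  one-leg jumps (LJ, RJ) are exact mirror images under a lateral-axis sign
  flip and are deliberately the most confusable pair;
* per-subject variation (frequency, amplitude, arm swing, asymmetry, noise)
  large enough that leave-one-subject-out splits are harder than random ones.

All randomness flows through explicit seeds; cohort generation is a pure
function of its seed.  Axis convention: x = along the forearm (arm swing),
y = lateral, z = vertical; gravity contributes a roughly unit-norm offset.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .signal_core import (
    LABEL_ORDER,
    DatasetManifest,
    ManifestEntry,
    MotionLabel,
    Recording,
    write_recording,
)

__all__ = [
    "SubjectProfile",
    "ClassSignalSpec",
    "DEFAULT_CLASS_SPECS",
    "draw_subject_profile",
    "generate_recording",
    "generate_cohort_recordings",
    "generate_cohort",
]


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject signal idiosyncrasies, all reproducible from ``rng_seed``."""

    subject_id: str
    bounce_freq_hz: float      # preferred bounce cadence, drawn in 1.2-2.6 Hz
    amplitude_scale: float     # overall vigor multiplier
    arm_swing_gain: float      # 0..1, how much the arm swings at half cadence
    noise_sd_g: float          # white sensor+tremor noise, G
    asymmetry_gain: float      # 0..1, strength of left/right alternation
    rng_seed: int


@dataclass(frozen=True)
class ClassSignalSpec:
    """What distinguishes one motion class from another, before subject traits."""

    label: MotionLabel
    vertical_amp_g: float
    periodic: bool
    alternation: str                      # none | left-right | left-only | right-only
    baseline_offset_g: tuple[float, float, float]
    freq_scale: float = 1.0               # carrier = freq_scale * subject cadence

    def __post_init__(self) -> None:
        if self.alternation not in ("none", "left-right", "left-only", "right-only"):
            raise ValueError(f"unknown alternation {self.alternation!r}")


# One-leg jumps share a spec body and differ only in the alternation side; the
# generator mirrors the entire lateral channel, so LJ and RJ are exact mirror
# images given identical seeds.
_ONE_LEG = dict(
    vertical_amp_g=0.80,
    periodic=True,
    baseline_offset_g=(0.15, 0.10, -0.92),
)

DEFAULT_CLASS_SPECS: dict[MotionLabel, ClassSignalSpec] = {
    MotionLabel.ST: ClassSignalSpec(
        MotionLabel.ST, 0.0, False, "none", (0.0, 0.0, -1.0)
    ),
    MotionLabel.WL: ClassSignalSpec(
        MotionLabel.WL, 0.35, True, "left-right", (0.10, 0.0, -0.98), freq_scale=0.7
    ),
    MotionLabel.MR: ClassSignalSpec(
        MotionLabel.MR, 0.55, True, "left-right", (0.15, 0.05, -0.95)
    ),
    MotionLabel.TJ: ClassSignalSpec(
        MotionLabel.TJ, 1.10, True, "none", (0.20, 0.0, -0.90)
    ),
    MotionLabel.LJ: ClassSignalSpec(MotionLabel.LJ, alternation="left-only", **_ONE_LEG),
    MotionLabel.RJ: ClassSignalSpec(MotionLabel.RJ, alternation="right-only", **_ONE_LEG),
}


def draw_subject_profile(
    subject_id: str, seed: int | np.random.SeedSequence
) -> SubjectProfile:
    """Draw one subject's traits; continuous distributions, so two subjects
    coincide with probability zero."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    return SubjectProfile(
        subject_id=subject_id,
        bounce_freq_hz=float(rng.uniform(1.2, 2.6)),
        amplitude_scale=float(rng.uniform(0.75, 1.30)),
        arm_swing_gain=float(rng.uniform(0.20, 0.90)),
        noise_sd_g=float(rng.uniform(0.03, 0.08)),
        asymmetry_gain=float(rng.uniform(0.50, 0.90)),
        rng_seed=int(ss.generate_state(1)[0] % (2**31)),
    )


def generate_recording(
    profile: SubjectProfile,
    spec: ClassSignalSpec,
    duration_s: float = 10.0,
    rate_hz: float = 100.0,
    seed: int | np.random.SeedSequence | None = None,
    set_index: int = 1,
) -> Recording:
    """Synthesize one labeled bout.

    Identical (profile, spec, seed, duration, rate) inputs reproduce identical
    samples.  ``seed`` defaults to ``profile.rng_seed``; a cohort passes a
    distinct spawned seed per (subject, set, motion).
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration_s and rate_hz must be positive")
    rng = np.random.default_rng(profile.rng_seed if seed is None else seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz

    # per-bout draws (same draw order regardless of class, so mirror classes
    # consume identical random streams)
    h2 = rng.uniform(0.30, 0.60)
    h3 = rng.uniform(0.10, 0.30)
    phi0 = rng.uniform(0.0, 2 * np.pi)
    psi2 = rng.uniform(0.0, 2 * np.pi)
    psi3 = rng.uniform(0.0, 2 * np.pi)
    phi_arm = rng.uniform(0.0, 2 * np.pi)
    phi_lat = rng.uniform(0.0, 2 * np.pi)
    phi_mod = rng.uniform(0.0, 2 * np.pi)
    # cadence jitter makes the signal quasi-periodic; walking is sloppier
    jitter_sd = 0.05 if spec.freq_scale < 1.0 else 0.015
    jitter = np.cumsum(rng.normal(0.0, jitter_sd, n))
    noise = rng.normal(0.0, profile.noise_sd_g, (n, 3))

    # gravity has unit magnitude in G at quasi-static posture, whatever the
    # wrist orientation; normalize so classes differ by direction, not norm
    g = np.asarray(spec.baseline_offset_g, dtype=float)
    g = g / np.linalg.norm(g)
    x = np.full(n, g[0])
    y = np.full(n, g[1])
    z = np.full(n, g[2])

    if spec.periodic and spec.vertical_amp_g > 0:
        f0 = profile.bounce_freq_hz * spec.freq_scale
        phase = 2 * np.pi * f0 * t + phi0 + jitter
        carrier = (
            np.cos(phase)
            + h2 * np.cos(2 * phase + psi2)
            + h3 * np.cos(3 * phase + psi3)
        )
        amp = spec.vertical_amp_g * profile.amplitude_scale

        if spec.alternation == "left-right":
            # leg alternates every bounce cycle -> amplitude modulation and a
            # lateral sway at half the carrier frequency (sub-harmonic)
            envelope = 1.0 + profile.asymmetry_gain * 0.5 * np.cos(phase / 2 + phi_mod)
            y = y + amp * 0.50 * profile.asymmetry_gain * np.cos(phase / 2 + phi_lat)
        elif spec.alternation in ("left-only", "right-only"):
            # same leg every bounce: no sub-harmonic, but a sustained one-sided
            # lateral lean plus lateral push at the carrier frequency
            envelope = 1.0
            y = y + amp * (
                0.20 * profile.asymmetry_gain
                + 0.25 * np.cos(phase + phi_lat)
            )
        else:
            envelope = 1.0
            y = y + amp * 0.08 * np.cos(phase + phi_lat)

        z = z + amp * envelope * carrier
        # the wrist swings at half the bounce cadence along the forearm axis,
        # and tilts with each bounce (gravity rotates in the device frame)
        x = x + profile.arm_swing_gain * amp * 0.30 * np.cos(phase / 2 + phi_arm)
        x = x + amp * 0.35 * np.cos(phase + psi2)

    values = np.column_stack([x, y, z]) + noise
    if spec.alternation == "right-only":
        values[:, 1] = -values[:, 1]

    return Recording(
        subject_id=profile.subject_id,
        set_index=set_index,
        label=spec.label,
        sample_rate_hz=rate_hz,
        t=t,
        values=values,
    )


def _subject_ids(n: int) -> list[str]:
    letters = string.ascii_uppercase
    return [
        letters[i] if n <= len(letters) else f"S{i + 1:02d}" for i in range(n)
    ]


def generate_cohort_recordings(
    n_subjects: int = 8,
    n_sets: int = 5,
    seed: int = 0,
    duration_s: float = 10.0,
    rate_hz: float = 100.0,
    class_specs: dict[MotionLabel, ClassSignalSpec] = DEFAULT_CLASS_SPECS,
) -> tuple[list[SubjectProfile], list[Recording]]:
    """Generate the full cohort in memory: per subject and set, one recording
    per motion in protocol order (ST, WL, MR, TJ, LJ, RJ)."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_subjects)
    profiles: list[SubjectProfile] = []
    recordings: list[Recording] = []
    for sid, sseq in zip(_subject_ids(n_subjects), subject_seeds):
        profile = draw_subject_profile(sid, sseq)
        profiles.append(profile)
        bout_seeds = iter(sseq.spawn(n_sets * len(LABEL_ORDER)))
        for set_index in range(1, n_sets + 1):
            for label in LABEL_ORDER:
                recordings.append(
                    generate_recording(
                        profile,
                        class_specs[label],
                        duration_s=duration_s,
                        rate_hz=rate_hz,
                        seed=next(bout_seeds),
                        set_index=set_index,
                    )
                )
    return profiles, recordings


def generate_cohort(
    out_dir: str | Path,
    n_subjects: int = 8,
    n_sets: int = 5,
    seed: int = 0,
    duration_s: float = 10.0,
    rate_hz: float = 100.0,
    overwrite: bool = False,
) -> DatasetManifest:
    """Generate a cohort and write it as sensor-log CSVs plus a manifest.

    Refuses to write into an existing non-empty directory unless ``overwrite``
    is set.  Byte-identical output for identical seeds.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out_dir} exists and is not empty; pass overwrite=True to replace"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    _, recordings = generate_cohort_recordings(
        n_subjects=n_subjects, n_sets=n_sets, seed=seed,
        duration_s=duration_s, rate_hz=rate_hz,
    )
    entries = []
    for rec in recordings:
        fname = f"{rec.subject_id}_set{rec.set_index}_{rec.label.code}.csv"
        write_recording(rec, out_dir / fname)
        entries.append(
            ManifestEntry(
                file_path=fname,
                subject_id=rec.subject_id,
                set_index=rec.set_index,
                label=rec.label,
                sample_rate_hz=rate_hz,
            )
        )
    manifest = DatasetManifest(entries=entries)
    manifest.write(out_dir / "manifest.csv")
    return manifest
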