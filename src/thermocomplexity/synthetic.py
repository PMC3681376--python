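"""Synthetic cohort generator for temperature complexity studies.

Generates 24-hour, 0.1-Hz skin-temperature surrogates whose structure mirrors
what is reported for systemic inflammation: band-limited oscillations in the
neurogenic (0.025-0.05 Hz), metabolic (0.00625-0.025 Hz) and ultradian
(below 0.00625 Hz) ranges, a slow linear drift, white measurement noise,
0.05 degC sensor quantization, small unannotated transient disturbances, and
optional annotated artifact segments.

Signal model per band: a mixture of broadband band-passed Gaussian noise
(``regularity = 0``, irregular/high entropy) and a slowly phase-drifting
sinusoid at a subject-specific frequency inside the band (``regularity = 1``,
near-periodic/low entropy).  Oscillation amplitudes sit near the sensor
resolution, so low-variability near-periodic signals reduce to staircases
with sparse quantization transients -- the "decomplexified" signature
attributed to septic shock -- while broadband profiles cross quantization
levels densely.  Between-subject variation (baseline spread, log-normal
amplitude and noise jitter, random rhythm frequency, shared transient
disturbances) makes amplitude-dependent features overlap between groups, so
group contrasts are carried by the complexity (entropy) features rather than
by raw energies or mean temperature, as observed in the study population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .signals import TemperatureSignal

BAND_NAMES = ("neurogenic", "metabolic", "ultradian")

#: Group labels used throughout the package.
GROUPS = ("SIRS", "sepsis", "septic_shock")

#: Synthetic SOFA score ranges (uniform integers, inclusive) per group.
#: Only the ordering shock > sepsis >= SIRS is meaningful.
SOFA_RANGES = {"SIRS": (8, 12), "sepsis": (9, 13), "septic_shock": (13, 18)}


def band_edges_hz(fs_hz: float = 0.1) -> dict[str, tuple[float, float]]:
    """Nominal physiological band edges in Hz for a given sampling rate.

    The neurogenic and metabolic bands are fixed; the ultradian band extends
    from the deepest dyadic analysis edge ``fs / 2**10`` up to the metabolic
    lower edge.
    """
    return {
        "neurogenic": (0.025, 0.05),
        "metabolic": (0.00625, 0.025),
        "ultradian": (fs_hz / 2**10, 0.00625),
    }


@dataclass
class GroupProfile:
    """Spectral and complexity profile of one patient group.

    Parameters
    ----------
    name:
        Group label.
    baseline_c:
        Mean temperature in degC (must lie in [35, 41]).
    baseline_sd_c:
        Between-subject SD of the baseline; group baselines overlap.
    trend_c_per_h:
        Linear drift in degC per hour.
    band_amplitudes:
        RMS amplitude in degC of each band component.
    band_regularity:
        Per-band value in [0, 1]: 0 is broadband filtered noise (irregular,
        high entropy), 1 is a pure slowly drifting sinusoid at a
        subject-specific frequency (near-periodic, low entropy).
    noise_sd_c:
        Standard deviation of white measurement noise in degC.
    amplitude_jitter, noise_jitter:
        Log-normal sigmas of per-subject multiplicative variation of the band
        amplitudes and the noise SD.  They make raw energies overlap between
        groups so that group contrasts are carried by regularity (entropy).
    """

    name: str
    baseline_c: float
    trend_c_per_h: float
    band_amplitudes: dict[str, float]
    band_regularity: dict[str, float]
    noise_sd_c: float
    baseline_sd_c: float = 0.6
    amplitude_jitter: float = 0.7
    noise_jitter: float = 0.5

    def __post_init__(self) -> None:
        if not 35.0 <= self.baseline_c <= 41.0:
            raise ValueError(f"baseline_c must be in [35, 41], got {self.baseline_c}")
        for band in BAND_NAMES:
            a = self.band_amplitudes.get(band, 0.0)
            r = self.band_regularity.get(band, 0.0)
            if a < 0:
                raise ValueError(f"amplitude for band {band!r} must be >= 0")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"regularity for band {band!r} must be in [0, 1]")
        if self.noise_sd_c < 0:
            raise ValueError("noise_sd_c must be >= 0")
        if min(self.baseline_sd_c, self.amplitude_jitter, self.noise_jitter) < 0:
            raise ValueError("jitter parameters must be >= 0")


@dataclass
class SyntheticCohortConfig:
    """Cohort-level simulation settings.

    Defaults follow the study design: 24-hour recordings at 0.1 Hz with a
    0.05 degC sensor resolution.  ``disturbance_rate`` controls small
    unannotated transient perturbations (sensor contact, movement) shared by
    every group; ``artifact_rate`` controls the larger annotated artifact
    segments that the preprocessing stage repairs.
    """

    n_per_group: int = 20
    duration_s: float = 86400.0
    fs_hz: float = 0.1
    quantization_c: float = 0.05
    artifact_rate: float = 1.0
    disturbance_rate: float = 5.0
    disturbance_sd_c: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs_hz <= 0:
            raise ValueError("duration_s and fs_hz must be positive")
        if self.duration_s * self.fs_hz < 2**10:
            raise ValueError(
                "duration_s * fs_hz must be at least 1024 samples so that "
                "nine dyadic wavelet scales exist"
            )
        if self.quantization_c < 0:
            raise ValueError("quantization_c must be >= 0 (0 disables quantization)")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.artifact_rate < 0 or self.disturbance_rate < 0:
            raise ValueError("rates must be >= 0")


def default_profiles() -> list[GroupProfile]:
    """Shipped group profiles.

    All groups share the neurogenic/metabolic structure and overlapping
    baseline and amplitude distributions; they differ in the regularity of
    the ultradian band (SIRS broadband, septic shock near-periodic, sepsis
    intermediate) and in measurement-noise level, so that the group contrast
    is concentrated in the ultradian-band complexity features.
    """
    return [
        GroupProfile(
            name="SIRS",
            baseline_c=38.3,
            trend_c_per_h=0.015,
            band_amplitudes={"neurogenic": 0.03, "metabolic": 0.04, "ultradian": 0.06},
            band_regularity={"neurogenic": 0.4, "metabolic": 0.45, "ultradian": 0.1},
            noise_sd_c=0.008,
        ),
        GroupProfile(
            name="sepsis",
            baseline_c=38.2,
            trend_c_per_h=0.02,
            band_amplitudes={"neurogenic": 0.03, "metabolic": 0.04, "ultradian": 0.06},
            band_regularity={"neurogenic": 0.4, "metabolic": 0.45, "ultradian": 0.85},
            noise_sd_c=0.005,
        ),
        GroupProfile(
            name="septic_shock",
            baseline_c=38.7,
            trend_c_per_h=0.03,
            band_amplitudes={"neurogenic": 0.03, "metabolic": 0.04, "ultradian": 0.055},
            band_regularity={"neurogenic": 0.4, "metabolic": 0.45, "ultradian": 0.9},
            noise_sd_c=0.0045,
        ),
    ]


def _bandpass_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise brick-wall filtered to [lo, hi] Hz (zero phase)."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _regular_tone(rng: np.random.Generator, t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS sinusoid with random phase and slow phase jitter.

    The tone frequency is subject-specific, log-uniform over the slow part
    of the band: a patient's dominant slow rhythm, not a fixed
    population-wide frequency.
    """
    u = rng.uniform(0.1, 0.45)
    fc = lo * (hi / lo) ** u
    jitter = np.cumsum(rng.standard_normal(len(t))) * 0.001
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return np.sqrt(2.0) * np.sin(2.0 * np.pi * fc * t + phase + jitter)


def generate_subject(
    profile: GroupProfile, config: SyntheticCohortConfig, seed: int
) -> TemperatureSignal:
    """Simulate one subject's recording; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    n = int(np.floor(config.duration_s * config.fs_hz))
    t = np.arange(n) / config.fs_hz
    baseline = profile.baseline_c
    if profile.baseline_sd_c > 0:
        baseline = float(np.clip(rng.normal(baseline, profile.baseline_sd_c), 35.5, 40.5))
    x = baseline + profile.trend_c_per_h * t / 3600.0
    edges = band_edges_hz(config.fs_hz)
    for band in BAND_NAMES:
        amp = profile.band_amplitudes.get(band, 0.0)
        if amp == 0.0:
            continue
        if profile.amplitude_jitter > 0:
            amp = amp * float(np.exp(rng.normal(0.0, profile.amplitude_jitter)))
        reg = profile.band_regularity.get(band, 0.0)
        lo, hi = edges[band]
        comp = (1.0 - reg) * _bandpass_noise(rng, n, config.fs_hz, lo, hi)
        comp += reg * _regular_tone(rng, t, lo, hi)
        # keep the component's RMS equal to amp regardless of the mix
        comp /= np.sqrt((1.0 - reg) ** 2 + reg**2)
        x = x + amp * comp
    if profile.noise_sd_c > 0:
        sd = profile.noise_sd_c * float(np.exp(rng.normal(0.0, profile.noise_jitter)))
        x = x + rng.normal(0.0, sd, size=n)
    if config.disturbance_rate > 0:
        # small unannotated transients (contact/movement), identical law for
        # all groups; they dominate raw band energies but not entropies
        for _ in range(int(rng.poisson(config.disturbance_rate))):
            dur = int(rng.uniform(3, min(60, n // 4)))
            start = int(rng.integers(0, n - dur))
            bump = rng.normal(0.0, config.disturbance_sd_c)
            x[start : start + dur] += bump * np.hanning(dur + 2)[1:-1]
    if config.quantization_c > 0:
        # round-half-even onto the sensor resolution grid
        x = np.round(x / config.quantization_c) * config.quantization_c
    return TemperatureSignal(samples=x, fs_hz=config.fs_hz, group=profile.name)


def inject_artifacts(
    signal: TemperatureSignal, n_segments: int, max_len_s: float, seed: int
) -> TemperatureSignal:
    """Corrupt a signal with flat dropouts or step offsets, recording the mask.

    Returns a new signal whose ``artifact_mask`` lists the injected intervals
    (disjoint, within bounds).  ``n_segments = 0`` returns an identical copy.
    """
    if n_segments < 0:
        raise ValueError("n_segments must be >= 0")
    if max_len_s >= signal.duration_s / 4:
        raise ValueError("max_len_s must be below a quarter of the signal duration")
    if n_segments == 0:
        return signal.with_(samples=signal.samples.copy(), artifact_mask=[])
    rng = np.random.default_rng(seed)
    n = signal.n_samples
    max_len = max(2, int(max_len_s * signal.fs_hz))
    x = signal.samples.copy()
    intervals: list[tuple[int, int]] = []
    attempts = 0
    while len(intervals) < n_segments and attempts < 1000 * n_segments:
        attempts += 1
        length = int(rng.integers(2, max_len + 1))
        start = int(rng.integers(1, n - length - 1))
        cand = (start, start + length)
        if any(cand[0] < j and i < cand[1] for i, j in intervals):
            continue
        if rng.random() < 0.5:  # flat dropout: sensor sticks at last value
            x[cand[0] : cand[1]] = x[cand[0] - 1]
        else:  # contact artifact: step offset
            x[cand[0] : cand[1]] += rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 2.0)
        intervals.append(cand)
    if len(intervals) < n_segments:
        warnings.warn("could not place all requested artifact segments disjointly")
    return signal.with_(samples=x, artifact_mask=sorted(intervals))


def generate_cohort(
    profiles: Sequence[GroupProfile], config: SyntheticCohortConfig
) -> list[TemperatureSignal]:
    """Simulate ``n_per_group`` subjects per profile with synthetic SOFA scores.

    Per-subject seeds are derived deterministically from ``config.seed``.
    The expected number of annotated artifact segments per signal is
    ``config.artifact_rate`` (Poisson distributed).
    """
    if len(profiles) == 0:
        raise ValueError("at least one group profile is required")
    root = np.random.default_rng(config.seed)
    signals: list[TemperatureSignal] = []
    idx = 0
    for profile in profiles:
        lo, hi = SOFA_RANGES.get(profile.name, (8, 18))
        for _ in range(config.n_per_group):
            sub_seed = int(root.integers(0, 2**31 - 1))
            sig = generate_subject(profile, config, seed=sub_seed)
            if config.artifact_rate > 0:
                n_seg = int(np.random.default_rng(sub_seed + 1).poisson(config.artifact_rate))
                if n_seg:
                    sig = inject_artifacts(
                        sig, n_seg, max_len_s=min(600.0, sig.duration_s / 5), seed=sub_seed + 2
                    )
            sofa = int(np.random.default_rng(sub_seed + 3).integers(lo, hi + 1))
            idx += 1
            signals.append(
                sig.with_(subject_id=f"S{idx:03d}", group=profile.name, sofa=sofa)
            )
    return signals


def write_cohort(signals: Sequence[TemperatureSignal], outdir: str | Path) -> Path:
    """Write one CSV per subject plus artifact masks and a cohort manifest.

    Returns the manifest path.  Manifest columns: subject_id, file, mask_file,
    group, sofa.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sig in signals:
        stem = sig.subject_id or "subject"
        fname = f"{stem}.csv"
        mname = f"{stem}_mask.csv"
        sig.write_csv(outdir / fname, outdir / mname)
        rows.append(
            {
                "subject_id": sig.subject_id,
                "file": fname,
                "mask_file": mname,
                "group": sig.group,
                "sofa": sig.sofa,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
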