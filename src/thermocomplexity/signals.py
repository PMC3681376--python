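"""Container for continuously monitored temperature recordings.

A recording is a regularly sampled single-channel series (degrees Celsius)
with an optional artifact mask of half-open sample-index intervals ``[i, j)``
and subject metadata.  The ``variant`` tag tracks preprocessing provenance:
``raw`` -> ``sign_m`` (mean removed) -> ``sign_mdetr`` (mean and linear
trend removed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

VARIANTS = ("raw", "sign_m", "sign_mdetr")

Interval = tuple[int, int]


def _validate_mask(mask: Sequence[Interval], n: int) -> list[Interval]:
    out: list[Interval] = []
    prev_end = 0
    for k, (i, j) in enumerate(sorted((int(a), int(b)) for a, b in mask)):
        if not 0 <= i < j <= n:
            raise ValueError(
                f"artifact interval [{i}, {j}) out of bounds for signal of length {n}"
            )
        if out and i < prev_end:
            raise ValueError(f"artifact intervals overlap at index {i}")
        out.append((i, j))
        prev_end = j
    return out


@dataclass
class TemperatureSignal:
    """A temperature recording with artifact annotations and metadata."""

    samples: np.ndarray
    fs_hz: float
    artifact_mask: list[Interval] = field(default_factory=list)
    subject_id: str | None = None
    group: str | None = None
    sofa: int | None = None
    variant: str = "raw"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs_hz > 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        self.artifact_mask = _validate_mask(self.artifact_mask, len(self.samples))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def mask_bool(self) -> np.ndarray:
        """Boolean array that is True inside artifact intervals."""
        b = np.zeros(self.n_samples, dtype=bool)
        for i, j in self.artifact_mask:
            b[i:j] = True
        return b

    def with_(self, **changes) -> "TemperatureSignal":
        return replace(self, **changes)

    # ---------------------------------------------------------------- I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times_s, "temp_C": self.samples})

    def write_csv(self, path: str | Path, mask_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, index=False)
        if mask_path is not None:
            rows = [
                {"start_s": i / self.fs_hz, "end_s": j / self.fs_hz}
                for i, j in self.artifact_mask
            ]
            pd.DataFrame(rows, columns=["start_s", "end_s"]).to_csv(mask_path, index=False)


def mask_from_seconds(
    intervals_s: Sequence[tuple[float, float]], fs_hz: float, n_samples: int
) -> list[Interval]:
    """Convert second-based artifact intervals to half-open sample indices.

    Start indices are floored and end indices ceiled so that the sample mask
    always covers the annotated time span.
    """
    out = []
    for start_s, end_s in intervals_s:
        i = int(math.floor(start_s * fs_hz))
        j = int(math.ceil(end_s * fs_hz))
        out.append((max(i, 0), min(j, n_samples)))
    return _validate_mask(out, n_samples)


def read_signal_csv(
    path: str | Path,
    mask_path: str | Path | None = None,
    fs_hz: float | None = None,
    **metadata,
) -> TemperatureSignal:
    """Read a subject CSV (``time_s, temp_C``) and optional mask CSV."""
    df = pd.read_csv(path)
    for col in ("time_s", "temp_C"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if fs_hz is None:
        dt = np.diff(df["time_s"].to_numpy())
        if len(dt) == 0 or not np.allclose(dt, dt[0]):
            raise ValueError(f"{path}: cannot infer sampling frequency from time_s")
        fs_hz = 1.0 / float(dt[0])
    samples = df["temp_C"].to_numpy(dtype=float)
    mask: list[Interval] = []
    if mask_path is not None and Path(mask_path).exists():
        mdf = pd.read_csv(mask_path)
        if len(mdf):
            mask = mask_from_seconds(
                list(zip(mdf["start_s"], mdf["end_s"])), fs_hz, len(samples)
            )
    return TemperatureSignal(samples=samples, fs_hz=fs_hz, artifact_mask=mask, **metadata)
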