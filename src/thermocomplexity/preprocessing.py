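"""Preprocessing of raw temperature recordings.

The sanctioned order is: repair annotated artifacts by linear interpolation,
subtract the mean (variant ``sign_m``), then remove the least-squares linear
trend (variant ``sign_mdetr``).  Mean removal keeps downstream features from
being biased by absolute temperature; detrending isolates the oscillatory
content from slow drift.
"""

from __future__ import annotations

import warnings

import numpy as np

from .signals import TemperatureSignal


def replace_artifacts(signal: TemperatureSignal) -> TemperatureSignal:
    """Replace each masked segment with the straight line joining the last
    clean sample before it and the first clean sample after it.

    Segments touching the record boundary are filled flat with the nearest
    clean value (with a warning).  A mask covering the whole record is an
    error.  Values outside the mask are returned bit-identical.
    """
    if signal.n_samples < 2:
        raise ValueError("signal must have at least 2 samples")
    x = signal.samples.copy()
    n = len(x)
    for i, j in signal.artifact_mask:
        if i == 0 and j == n:
            raise ValueError("artifact mask covers the entire signal")
        if i == 0:
            warnings.warn("artifact interval touches the signal start; filling flat")
            x[i:j] = x[j]
        elif j == n:
            warnings.warn("artifact interval touches the signal end; filling flat")
            x[i:j] = x[i - 1]
        else:
            # line between the bracketing clean samples x[i-1] and x[j]
            x[i:j] = np.interp(np.arange(i, j), [i - 1, j], [x[i - 1], x[j]])
    return signal.with_(samples=x)


def remove_mean(signal: TemperatureSignal) -> TemperatureSignal:
    """Subtract the record mean, producing the ``sign_m`` variant."""
    if signal.n_samples == 0:
        raise ValueError("cannot remove the mean of an empty signal")
    x = signal.samples - signal.samples.mean()
    return signal.with_(samples=x, variant="sign_m")


def detrend_linear(signal: TemperatureSignal) -> TemperatureSignal:
    """Remove the ordinary-least-squares line fit over the full record,
    producing the ``sign_mdetr`` variant."""
    if signal.n_samples < 2:
        raise ValueError("detrending requires at least 2 samples")
    x = signal.samples
    t = np.arange(len(x), dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    resid = x - (slope * t + intercept)
    return signal.with_(samples=resid, variant="sign_mdetr")


def flag_artifact_jumps(signal: TemperatureSignal, threshold_c: float = 0.5) -> list[tuple[int, int]]:
    """Optional automatic artifact flagging: single-sample jumps larger than
    ``threshold_c`` degC.  Off by default in the pipeline; annotation of real
    recordings is expected to be manual."""
    jumps = np.flatnonzero(np.abs(np.diff(signal.samples)) > threshold_c)
    return [(int(k) + 1, int(k) + 2) for k in jumps]


def preprocess(signal: TemperatureSignal) -> dict[str, TemperatureSignal]:
    """Run the full chain and return both analysis variants.

    Returns a dict with keys ``sign_m`` and ``sign_mdetr``; the repaired raw
    signal is available under ``raw``.
    """
    repaired = replace_artifacts(signal)
    sign_m = remove_mean(repaired)
    sign_mdetr = detrend_linear(sign_m)
    return {"raw": repaired, "sign_m": sign_m, "sign_mdetr": sign_mdetr}
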