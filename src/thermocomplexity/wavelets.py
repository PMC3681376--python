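"""Meyer-wavelet time-scale features.

Implements a dyadic discrete wavelet transform and a continuous wavelet
transform with the Meyer wavelet, both evaluated exactly in the Fourier
domain.  The Meyer scaling function and wavelet are band-limited with
closed-form Fourier transforms, so the filter bank uses the exact conjugate
mirror filter rather than a truncated FIR approximation; with periodic
boundary handling the transform is orthonormal to machine precision and
Parseval's identity holds exactly.  Each detail scale ``i`` is confined to
the dyadic band ``[fs / 2**(i+1), fs / 2**i]``.

Per-scale features: wavelet energy ``WE(s_i)`` (mean squared coefficient,
variability in the band) and wavelet entropy ``WEn(s_i)`` (Shannon entropy
of the normalized squared-coefficient distribution within the scale,
temporal irregularity of the band's activity).  The continuous transform
yields energy/entropy over four physiological frequency bands and over the
whole time-scale map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .signals import TemperatureSignal

_LOG_BASES = {"natural": 1.0, "base-2": np.log(2.0), "base-10": np.log(10.0)}

#: Default frequency edges (Hz) of the four continuous-transform bands at
#: fs = 0.1 Hz: neurogenic, metabolic, lower metabolic/ultradian, ultradian.
#: Bands 1-2 coincide with dyadic scales 1 and 2-3; bands 3-4 split the
#: remaining ultradian range at the scale-5 edge.
def default_cwt_bands(fs_hz: float = 0.1) -> dict[str, tuple[float, float]]:
    return {
        "band1": (0.025, 0.05),
        "band2": (0.00625, 0.025),
        "band3": (0.0015625, 0.00625),
        "band4": (fs_hz / 2**10, 0.0015625),
    }


# --------------------------------------------------------------- Meyer math

def _nu(x: np.ndarray) -> np.ndarray:
    """Meyer auxiliary polynomial, smooth 0 -> 1 on [0, 1]."""
    x = np.clip(x, 0.0, 1.0)
    return x**4 * (35.0 - 84.0 * x + 70.0 * x**2 - 20.0 * x**3)


def _phi_hat(u: np.ndarray) -> np.ndarray:
    """Fourier transform of the Meyer scaling function (real, compact support)."""
    au = np.abs(u)
    return np.where(
        au <= 2 * np.pi / 3,
        1.0,
        np.where(
            au <= 4 * np.pi / 3,
            np.cos(np.pi / 2 * _nu(3 * au / (2 * np.pi) - 1.0)),
            0.0,
        ),
    )


def _psi_hat(u: np.ndarray) -> np.ndarray:
    """Fourier transform of the Meyer mother wavelet.

    Supported on ``2*pi/3 <= |u| <= 8*pi/3`` with unit peak at ``|u| = 4*pi/3``.
    """
    au = np.abs(u)
    mag = np.where(
        (au >= 2 * np.pi / 3) & (au <= 4 * np.pi / 3),
        np.sin(np.pi / 2 * _nu(3 * au / (2 * np.pi) - 1.0)),
        np.where(
            (au > 4 * np.pi / 3) & (au <= 8 * np.pi / 3),
            np.cos(np.pi / 2 * _nu(3 * au / (4 * np.pi) - 1.0)),
            0.0,
        ),
    )
    return np.exp(1j * u / 2) * mag


def _meyer_cmf(omega: np.ndarray) -> np.ndarray:
    """Exact Meyer conjugate mirror filter, 2*pi-periodic.

    Satisfies ``|H(w)|**2 + |H(w + pi)|**2 = 2`` identically.
    """
    w = np.mod(omega + np.pi, 2 * np.pi) - np.pi
    return np.sqrt(2.0) * _phi_hat(2.0 * w)


def _dwt_step(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One level of the orthonormal Meyer filter bank (periodic, exact)."""
    n = len(a)
    spec = np.fft.fft(a)
    om = 2.0 * np.pi * np.arange(n) / n
    h = _meyer_cmf(om)
    g = np.exp(-1j * om) * np.conj(_meyer_cmf(om + np.pi))
    half = n // 2
    ca = np.conj(h) * spec
    cd = np.conj(g) * spec
    approx = np.fft.ifft(0.5 * (ca[:half] + ca[half:])).real
    detail = np.fft.ifft(0.5 * (cd[:half] + cd[half:])).real
    return approx, detail


# ---------------------------------------------------------------- scale map

@dataclass(frozen=True)
class ScaleBand:
    """Dyadic frequency band of one DWT scale, with period range in minutes."""

    scale: int
    f_min_hz: float
    f_max_hz: float
    period_min_min: float
    period_max_min: float
    tag: str


def scale_frequency_bands(fs_hz: float, n_scales: int = 9) -> list[ScaleBand]:
    """Map DWT scales to frequency bands and oscillation periods.

    Scale ``i`` covers ``[fs / 2**(i+1), fs / 2**i]`` Hz; periods are the
    reciprocal range in minutes.  Scale 1 is tagged neurogenic, scales 2-3
    metabolic, deeper scales ultradian.
    """
    if fs_hz <= 0 or n_scales < 1:
        raise ValueError("fs_hz must be positive and n_scales >= 1")
    bands = []
    for i in range(1, n_scales + 1):
        f_max = fs_hz / 2**i
        f_min = fs_hz / 2 ** (i + 1)
        tag = "neurogenic" if i == 1 else ("metabolic" if i <= 3 else "ultradian")
        bands.append(
            ScaleBand(
                scale=i,
                f_min_hz=f_min,
                f_max_hz=f_max,
                period_min_min=1.0 / (60.0 * f_max),
                period_max_min=1.0 / (60.0 * f_min),
                tag=tag,
            )
        )
    return bands


def scale_band_table(fs_hz: float = 0.1, n_scales: int = 9) -> pd.DataFrame:
    """The scale -> band map as a DataFrame (Hz and minute columns)."""
    return pd.DataFrame([vars(b) for b in scale_frequency_bands(fs_hz, n_scales)])


# -------------------------------------------------------------------- DWT

@dataclass
class WaveletDecomposition:
    """Detail coefficients per scale (1-based) plus the final approximation."""

    details: list[np.ndarray]
    approx: np.ndarray
    fs_hz: float
    wavelet: str = "meyer"
    boundary: str = "periodic"
    n_pad: int = 0

    @property
    def n_scales(self) -> int:
        return len(self.details)

    def coefficients(self, scale: int) -> np.ndarray:
        if not 1 <= scale <= self.n_scales:
            raise ValueError(f"scale must be in 1..{self.n_scales}, got {scale}")
        return self.details[scale - 1]


def dwt_decompose(
    signal: TemperatureSignal | np.ndarray,
    n_scales: int = 9,
    fs_hz: float | None = None,
) -> WaveletDecomposition:
    """Nine-scale (by default) Meyer DWT of a preprocessed signal.

    Signals whose length is not a multiple of ``2**n_scales`` are extended by
    reflection at the end so every filter-bank stage halves an even length;
    the few padded samples are retained in the coefficient vectors.
    """
    if isinstance(signal, TemperatureSignal):
        x = signal.samples
        fs_hz = signal.fs_hz
    else:
        x = np.asarray(signal, dtype=float)
        if fs_hz is None:
            raise ValueError("fs_hz is required when passing a bare array")
    n = len(x)
    min_n = 2 ** (n_scales + 1)
    if n < min_n:
        raise ValueError(
            f"signal of length {n} is too short for {n_scales} scales; "
            f"at least {min_n} samples are required"
        )
    block = 2**n_scales
    target = int(np.ceil(n / block)) * block
    n_pad = target - n
    if n_pad:
        x = np.concatenate([x, x[-2 : -n_pad - 2 : -1]])
    details: list[np.ndarray] = []
    a = x
    for _ in range(n_scales):
        a, d = _dwt_step(a)
        details.append(d)
    return WaveletDecomposition(details=details, approx=a, fs_hz=fs_hz, n_pad=n_pad)


def wavelet_energy(decomp: WaveletDecomposition, scale: int) -> float:
    """Mean squared wavelet coefficient at one scale."""
    w = decomp.coefficients(scale)
    if len(w) == 0:
        raise ValueError(f"no coefficients at scale {scale}")
    return float(np.mean(w**2))


def wavelet_entropy(
    decomp: WaveletDecomposition,
    scale: int,
    log_base: str = "natural",
    normalized: bool = False,
) -> float:
    """Shannon entropy of the normalized squared-coefficient distribution.

    Probabilities are ``p_j = w_j**2 / sum_j w_j**2`` within the scale, so the
    value lies in ``[0, log(L)]`` for ``L`` coefficients; ``normalized=True``
    divides by ``log(L)`` to give a [0, 1] irregularity index.  An all-zero
    scale is defined as entropy 0 (with a warning).
    """
    if log_base not in _LOG_BASES:
        raise ValueError(f"log_base must be one of {tuple(_LOG_BASES)}")
    w = decomp.coefficients(scale)
    if len(w) == 0:
        raise ValueError(f"no coefficients at scale {scale}")
    e = w**2
    total = e.sum()
    if total == 0.0:
        warnings.warn(f"all-zero coefficients at scale {scale}; entropy defined as 0")
        return 0.0
    p = e / total
    p = p[p > 0]
    ent = float(-(p * np.log(p)).sum()) / _LOG_BASES[log_base]
    if normalized:
        ent /= np.log(len(w)) / _LOG_BASES[log_base]
    return ent


def dwt_features(
    signal: TemperatureSignal | np.ndarray,
    n_scales: int = 9,
    fs_hz: float | None = None,
    log_base: str = "natural",
) -> dict[str, float]:
    """The 18 per-scale DWT features ``WE_s1..WE_s9`` and ``WEn_s1..WEn_s9``,
    plus normalized entropies ``WEn_norm_s1..``."""
    decomp = dwt_decompose(signal, n_scales=n_scales, fs_hz=fs_hz)
    out: dict[str, float] = {}
    for s in range(1, n_scales + 1):
        out[f"WE_s{s}"] = wavelet_energy(decomp, s)
    for s in range(1, n_scales + 1):
        out[f"WEn_s{s}"] = wavelet_entropy(decomp, s, log_base=log_base)
    for s in range(1, n_scales + 1):
        out[f"WEn_norm_s{s}"] = wavelet_entropy(decomp, s, log_base=log_base, normalized=True)
    return out


# -------------------------------------------------------------------- CWT

@dataclass
class CWTMap:
    """Continuous-wavelet coefficient map: rows ordered by decreasing
    pseudo-frequency, one column per sample."""

    coeffs: np.ndarray  # (n_freqs, n_samples), real
    pseudo_freqs_hz: np.ndarray  # descending
    fs_hz: float

    def __post_init__(self) -> None:
        if self.coeffs.shape[0] != len(self.pseudo_freqs_hz):
            raise ValueError("row count must match pseudo-frequency grid")


def cwt_map(
    signal: TemperatureSignal | np.ndarray,
    pseudo_freqs_hz: np.ndarray | None = None,
    n_freqs: int = 64,
    fs_hz: float | None = None,
) -> CWTMap:
    """Meyer CWT over a logarithmic pseudo-frequency grid.

    The default grid spans ``[fs / 2**10, fs / 2]`` with 64 points, covering
    all dyadic analysis bands.  For each target pseudo-frequency the wavelet
    is dilated so its spectral peak falls exactly on that frequency, and the
    coefficients are computed by frequency-domain multiplication with
    L1-style normalization: an oscillation of a given amplitude produces
    coefficients of the same magnitude whatever its frequency, so the row of
    maximal response identifies the oscillation frequency directly.
    """
    if isinstance(signal, TemperatureSignal):
        x = signal.samples
        fs_hz = signal.fs_hz
    else:
        x = np.asarray(signal, dtype=float)
        if fs_hz is None:
            raise ValueError("fs_hz is required when passing a bare array")
    n = len(x)
    if pseudo_freqs_hz is None:
        pseudo_freqs_hz = np.logspace(
            np.log10(fs_hz / 2**10), np.log10(fs_hz / 2), n_freqs
        )[::-1]
    pseudo_freqs_hz = np.asarray(pseudo_freqs_hz, dtype=float)
    if len(pseudo_freqs_hz) == 0:
        raise ValueError("pseudo-frequency grid is empty")
    if np.any(pseudo_freqs_hz <= 0) or np.any(pseudo_freqs_hz > fs_hz / 2):
        raise ValueError("pseudo-frequencies must lie in (0, fs/2]")
    pseudo_freqs_hz = np.sort(pseudo_freqs_hz)[::-1]
    spec = np.fft.fft(x)
    om = 2.0 * np.pi * np.fft.fftfreq(n)  # rad/sample in [-pi, pi)
    rows = np.empty((len(pseudo_freqs_hz), n))
    peak = 4.0 * np.pi / 3.0  # spectral peak of the mother wavelet
    for k, f in enumerate(pseudo_freqs_hz):
        a = peak * fs_hz / (2.0 * np.pi * f)  # dilation in samples
        rows[k] = np.fft.ifft(spec * np.conj(_psi_hat(a * om))).real
    return CWTMap(coeffs=rows, pseudo_freqs_hz=pseudo_freqs_hz, fs_hz=fs_hz)


def _cells_entropy(cells: np.ndarray, log_base: str, normalize: bool) -> float:
    e = cells**2
    total = e.sum()
    if total == 0.0:
        return 0.0
    p = (e / total).ravel()
    p = p[p > 0]
    ent = float(-(p * np.log(p)).sum()) / _LOG_BASES[log_base]
    if normalize:
        ent /= np.log(cells.size) / _LOG_BASES[log_base]
    return ent


def cwt_band_features(
    cmap: CWTMap,
    band_edges: dict[str, tuple[float, float]] | None = None,
    log_base: str = "natural",
) -> dict[str, float]:
    """Energy and entropy of the CWT map per band and over the whole map.

    Returns the 10 features ``CWTen``, ``CWTentro``, ``CWTen1..4`` and
    ``CWTentro1..4`` where the entropies are normalized by ``log`` of the
    number of cells (a [0, 1] index), plus the unnormalized values under a
    ``_raw`` suffix.  A band containing no grid rows is an error.
    """
    if band_edges is None:
        band_edges = default_cwt_bands(cmap.fs_hz)
    out: dict[str, float] = {}
    out["CWTen"] = float(np.mean(cmap.coeffs**2))
    out["CWTentro"] = _cells_entropy(cmap.coeffs, log_base, normalize=True)
    out["CWTentro_raw"] = _cells_entropy(cmap.coeffs, log_base, normalize=False)
    for k, (name, (lo, hi)) in enumerate(band_edges.items(), start=1):
        sel = (cmap.pseudo_freqs_hz >= lo) & (cmap.pseudo_freqs_hz <= hi)
        if not sel.any():
            raise ValueError(f"no pseudo-frequencies fall inside band {name!r} [{lo}, {hi}] Hz")
        cells = cmap.coeffs[sel]
        out[f"CWTen{k}"] = float(np.mean(cells**2))
        out[f"CWTentro{k}"] = _cells_entropy(cells, log_base, normalize=True)
        out[f"CWTentro{k}_raw"] = _cells_entropy(cells, log_base, normalize=False)
    return out


def cwt_features(
    signal: TemperatureSignal | np.ndarray,
    n_freqs: int = 64,
    fs_hz: float | None = None,
    log_base: str = "natural",
) -> dict[str, float]:
    """Convenience wrapper: CWT map plus band features."""
    cmap = cwt_map(signal, n_freqs=n_freqs, fs_hz=fs_hz)
    return cwt_band_features(cmap, log_base=log_base)


# ------------------------------------------------------------- transformer

class WaveletFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transform an array of equally long signals into wavelet features.

    Input to :meth:`transform` is ``(n_subjects, n_samples)``; output is a
    DataFrame with 18 DWT features (plus normalized entropies) and 10 CWT
    band features per row.  Stateless (``fit`` is a no-op), composable with
    scikit-learn pipelines.
    """

    def __init__(
        self,
        fs_hz: float = 0.1,
        n_scales: int = 9,
        n_freqs: int = 64,
        log_base: str = "natural",
    ):
        self.fs_hz = fs_hz
        self.n_scales = n_scales
        self.n_freqs = n_freqs
        self.log_base = log_base

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_subjects, n_samples)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_subjects, n_samples)")
        rows = []
        for x in X:
            feats = dwt_features(x, n_scales=self.n_scales, fs_hz=self.fs_hz,
                                 log_base=self.log_base)
            feats.update(cwt_features(x, n_freqs=self.n_freqs, fs_hz=self.fs_hz,
                                      log_base=self.log_base))
            rows.append(feats)
        return pd.DataFrame(rows)

    def get_feature_names_out(self, input_features=None):
        dummy = np.zeros((1, 2 ** (self.n_scales + 1)))
        dummy[0, 0] = 1.0
        return np.asarray(self.transform(dummy).columns, dtype=object)
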