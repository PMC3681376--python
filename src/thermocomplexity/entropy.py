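"""Sample entropy and multiscale entropy (MSE).

Sample entropy SampEn(m, r) is the negative natural logarithm of the
conditional probability that two sequences that match for m points (within
tolerance r, Chebyshev distance, self-matches excluded) still match at the
next point.  The MSE curve evaluates SampEn on coarse-grained copies of the
series at scale factors tau = 1..n_scales; the series is normalized to unit
standard deviation once, and the tolerance r (a fraction of that SD) is held
fixed across scales.  ``sumEn`` is the sum of the defined per-scale values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _template_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Counts of matching template pairs of length m (B) and m+1 (A)."""
    n = x.shape[0]
    a = 0
    b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            d = 0.0
            for k in range(m):
                dd = abs(x[i + k] - x[j + k])
                if dd > d:
                    d = dd
            if d <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sample_entropy(x: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """SampEn(m, r) with an absolute tolerance ``r_abs``.

    Returns ``nan`` (the undefined marker) when no template pairs match at
    either length; a constant series returns 0 (all templates match).
    """
    x = np.ascontiguousarray(np.asarray(x, dtype=float))
    if m < 1:
        raise ValueError("embedding dimension m must be >= 1")
    if len(x) <= m + 1:
        raise ValueError(f"series of length {len(x)} is too short for m={m}")
    if r_abs is None:
        sd = x.std()
        if sd == 0:
            raise ValueError("cannot derive tolerance from a zero-variance series")
        r_abs = 0.15 * sd
    if r_abs <= 0:
        raise ValueError("tolerance r_abs must be positive")
    a, b = _template_counts(x, m, r_abs)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Average non-overlapping windows of length tau; trailing remainder is
    dropped.  ``tau = 1`` returns the input unchanged."""
    x = np.asarray(x, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau > len(x):
        raise ValueError(f"tau={tau} exceeds series length {len(x)}")
    if tau == 1:
        return x
    n = len(x) // tau
    return x[: n * tau].reshape(n, tau).mean(axis=1)


@dataclass
class MSEParams:
    """MSE settings: embedding dimension m, tolerance r as a fraction of the
    (unit, post-normalization) SD, and the number of coarse-graining scales."""

    m: int = 2
    r: float = 0.15
    n_scales: int = 36

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 < self.r < 1.0:
            raise ValueError("r must be in (0, 1)")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")


@dataclass
class MSEResult:
    """SampEn per coarse-graining factor, with the undefined scales tracked."""

    scales: np.ndarray
    sampen_by_scale: np.ndarray  # nan where undefined
    base_sampen: float
    params: MSEParams = field(default_factory=MSEParams)

    @property
    def sum_en(self) -> float:
        """Sum of SampEn over the scales where it is defined."""
        return float(np.nansum(self.sampen_by_scale))

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.sampen_by_scale).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tau": self.scales, "sampen": self.sampen_by_scale})


def mse_curve(x: np.ndarray, params: MSEParams | None = None) -> MSEResult:
    """Multiscale entropy of a series.

    The series is normalized to SD = 1 once, and the absolute tolerance
    ``r`` is then held fixed for every coarse-grained scale (the coarse
    series are not re-normalized).  A zero-variance series is an error.
    """
    params = params or MSEParams()
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance series: MSE normalization impossible")
    x = (x - x.mean()) / sd
    values = np.full(params.n_scales, np.nan)
    for tau in range(1, params.n_scales + 1):
        n_coarse = len(x) // tau
        if n_coarse <= params.m + 1:
            raise ValueError(
                f"series too short at coarse-graining factor tau={tau}: "
                f"{n_coarse} points for m={params.m}"
            )
        values[tau - 1] = sample_entropy(coarse_grain(x, tau), params.m, params.r)
    return MSEResult(
        scales=np.arange(1, params.n_scales + 1),
        sampen_by_scale=values,
        base_sampen=values[0],
        params=params,
    )


def mse_features(x: np.ndarray, params: MSEParams | None = None) -> dict[str, float]:
    """The two feature-table columns: base SampEn and sumEn."""
    res = mse_curve(x, params)
    return {"SampEn": res.base_sampen, "sumEn": res.sum_en}


class MultiscaleEntropyTransformer(BaseEstimator, TransformerMixin):
    """scikit-learn transformer mapping ``(n_subjects, n_samples)`` signal
    arrays to the columns ``SampEn`` and ``sumEn``."""

    def __init__(self, m: int = 2, r: float = 0.15, n_scales: int = 36):
        self.m = m
        self.r = r
        self.n_scales = n_scales

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_subjects, n_samples)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        X = np.asarray(X, dtype=float)
        params = MSEParams(m=self.m, r=self.r, n_scales=self.n_scales)
        return pd.DataFrame([mse_features(x, params) for x in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["SampEn", "sumEn"], dtype=object)
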