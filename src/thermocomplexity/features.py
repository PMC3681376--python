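"""Assembly of the subject x feature table.

One row per subject and preprocessing variant.  Columns:

- metadata: ``subject_id``, ``group``, ``sofa``, ``variant``
- raw-signal descriptors: ``T_mean``, ``T_sd`` (after artifact repair)
- 18 DWT features ``WE_s1..WE_s9``, ``WEn_s1..WEn_s9`` plus normalized
  entropies ``WEn_norm_s1..``
- 10 CWT features ``CWTen``, ``CWTentro``, ``CWTen1..4``, ``CWTentro1..4``
  (normalized [0, 1] entropies) plus ``*_raw`` unnormalized entropies
- multiscale entropy: ``SampEn``, ``sumEn``

This table is the substrate for the statistical battery, clustering, and
classification stages.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .entropy import MSEParams, mse_features
from .preprocessing import preprocess
from .signals import TemperatureSignal
from .wavelets import cwt_features, dwt_features

META_COLUMNS = ("subject_id", "group", "sofa", "variant", "T_mean", "T_sd")

DEFAULT_VARIANTS = ("sign_m", "sign_mdetr")


def extract_features(
    signal: TemperatureSignal,
    variants: Sequence[str] = DEFAULT_VARIANTS,
    include_mse: bool = True,
    n_scales: int = 9,
    n_freqs: int = 64,
    log_base: str = "natural",
    mse_params: MSEParams | None = None,
) -> list[dict]:
    """Feature rows (one per variant) for a single raw signal."""
    processed = preprocess(signal)
    repaired = processed["raw"]
    rows = []
    for variant in variants:
        if variant not in processed:
            raise ValueError(f"unknown variant {variant!r}")
        sig = processed[variant]
        row: dict = {
            "subject_id": signal.subject_id,
            "group": signal.group,
            "sofa": signal.sofa,
            "variant": variant,
            "T_mean": float(repaired.samples.mean()),
            "T_sd": float(repaired.samples.std(ddof=1)),
        }
        row.update(dwt_features(sig, n_scales=n_scales, log_base=log_base))
        row.update(cwt_features(sig, n_freqs=n_freqs, log_base=log_base))
        if include_mse:
            row.update(mse_features(sig.samples, mse_params))
        rows.append(row)
    return rows


def extract_feature_table(
    signals: Sequence[TemperatureSignal],
    variants: Sequence[str] = DEFAULT_VARIANTS,
    include_mse: bool = True,
    **kwargs,
) -> pd.DataFrame:
    """Feature table for a cohort of raw signals (one row per subject and
    variant)."""
    rows: list[dict] = []
    for sig in signals:
        rows.extend(
            extract_features(sig, variants=variants, include_mse=include_mse, **kwargs)
        )
    return pd.DataFrame(rows)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the numeric feature columns (everything but metadata)."""
    return [c for c in table.columns if c not in META_COLUMNS]
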