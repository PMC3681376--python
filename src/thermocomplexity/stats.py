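"""Univariate statistical battery over the feature table.

Nonparametric tests matching small-cohort practice: Lilliefors normality
screening, pairwise Wilcoxon rank-sum tests, Kruskal-Wallis across the three
groups with Dunn-type multiple comparisons under Bonferroni correction (over
the three group pairs, not across features), Spearman rank correlation
against illness severity (SOFA), and one-way ANOVA for the variables that do
pass the normality screen (age, temperature).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

PAIR_KEYS = ((0, 1), (0, 2), (1, 2))


# ------------------------------------------------------------- normality

@lru_cache(maxsize=32)
def _lilliefors_null(n: int, n_sims: int, seed: int) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors statistic.

    The statistic is distribution-free given n (location and scale are
    estimated), so the null table is cached per sample size.
    """
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_sims, n))
    draws.sort(axis=1)
    mu = draws.mean(axis=1, keepdims=True)
    sd = draws.std(axis=1, ddof=1, keepdims=True)
    z = sps.norm.cdf((draws - mu) / sd)
    i = np.arange(1, n + 1)
    d_plus = (i / n - z).max(axis=1)
    d_minus = (z - (i - 1) / n).max(axis=1)
    return np.sort(np.maximum(d_plus, d_minus))


def lilliefors_test(x, n_sims: int = 10000, seed: int = 0) -> tuple[float, float]:
    """Lilliefors adaptation of the Kolmogorov-Smirnov normality test.

    Mean and SD are estimated from the data; the p-value comes from a seeded
    Monte-Carlo null (``n_sims`` draws).  Returns ``(statistic, p_value)``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 4:
        raise ValueError("Lilliefors test requires at least 4 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input")
    z = sps.norm.cdf((x - x.mean()) / sd)
    i = np.arange(1, n + 1)
    d = max((i / n - z).max(), (z - (i - 1) / n).max())
    null = _lilliefors_null(n, n_sims, seed)
    # upper-tail p with a continuity-style floor of 1/(n_sims + 1)
    p = (np.sum(null >= d) + 1) / (n_sims + 1)
    return float(d), float(p)


# ------------------------------------------------------------ rank tests

def _split_groups(values, labels) -> dict:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    return {g: values[labels == g] for g in pd.unique(labels)}


def ranksum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when the combined sample is small (n <= 20) and tie-free,
    a normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    combined = np.concatenate([x, y])
    exact = len(combined) <= 20 and len(np.unique(combined)) == len(combined)
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return float(res.pvalue)


def ranksum_pairwise(values, labels) -> dict[tuple, float]:
    """Pairwise two-sided rank-sum p-values over all group pairs."""
    groups = _split_groups(values, labels)
    names = list(groups)
    out = {}
    for a, b in itertools.combinations(names, 2):
        out[(a, b)] = ranksum(groups[a], groups[b])
    return out


def kruskal_wallis(values, labels) -> tuple[float, float, dict]:
    """Kruskal-Wallis H (tie corrected), chi-square p, and per-group mean ranks."""
    groups = _split_groups(values, labels)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    h, p = sps.kruskal(*groups.values())
    ranks = sps.rankdata(np.asarray(values, dtype=float))
    labels = np.asarray(labels)
    mean_ranks = {g: float(ranks[labels == g].mean()) for g in groups}
    return float(h), float(p), mean_ranks


def kw_multiple_comparison(values, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Dunn-type pairwise comparisons of Kruskal-Wallis mean ranks.

    Two-sided z-tests on rank-mean differences with tie-corrected variance,
    Bonferroni-adjusted over the observed pairs.  Returns a DataFrame with
    columns ``group1, group2, z, p_adj, significant``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    n = len(values)
    ranks = sps.rankdata(values)
    # tie correction for the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n**3 - n) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 * (1.0 - tie_term)
    pairs = list(itertools.combinations(groups, 2))
    rows = []
    for a, b in pairs:
        ra, rb = ranks[labels == a], ranks[labels == b]
        se = np.sqrt(var_base * (1.0 / len(ra) + 1.0 / len(rb)))
        z = (ra.mean() - rb.mean()) / se
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * len(pairs))
        rows.append(
            {"group1": a, "group2": b, "z": float(z),
             "p_adj": float(p_adj), "significant": bool(p_adj < alpha)}
        )
    return pd.DataFrame(rows)


def spearman_vs_severity(feature, sofa) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation between a feature and SOFA."""
    feature = np.asarray(feature, dtype=float)
    sofa = np.asarray(sofa, dtype=float)
    if len(feature) != len(sofa):
        raise ValueError("feature and sofa must have equal length")
    if len(feature) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(feature) == 0 or np.ptp(sofa) == 0:
        raise ValueError("constant input")
    rho, p = sps.spearmanr(feature, sofa)
    return float(rho), float(p)


def anova_oneway(values, labels) -> tuple[float, float]:
    """Classic one-way ANOVA F and p (for normally distributed variables)."""
    groups = _split_groups(values, labels)
    f, p = sps.f_oneway(*groups.values())
    return float(f), float(p)


# ---------------------------------------------------------- table builders

def _fmt_median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.3g} ({q1:.3g}-{q3:.3g})"


def group_comparison_table(
    table: pd.DataFrame,
    features: list[str],
    group_col: str = "group",
    variant: str | None = None,
) -> pd.DataFrame:
    """Feature-distribution summary: per-group ``median (q1-q3)`` strings,
    pairwise rank-sum p-values, and the Kruskal-Wallis p per feature."""
    df = table if variant is None else table[table["variant"] == variant]
    groups = list(pd.unique(df[group_col]))
    rows = []
    for feat in features:
        vals = df[feat].to_numpy(dtype=float)
        labs = df[group_col].to_numpy()
        row: dict = {"feature": feat}
        if variant is not None:
            row["variant"] = variant
        for g in groups:
            row[g] = _fmt_median_iqr(vals[labs == g])
        for (a, b), p in ranksum_pairwise(vals, labs).items():
            row[f"p {a} vs {b}"] = p
        if len(groups) >= 3:
            _, p_kw, _ = kruskal_wallis(vals, labs)
            row["p_kw"] = p_kw
        rows.append(row)
    return pd.DataFrame(rows)


def severity_correlation_table(
    table: pd.DataFrame, features: list[str], sofa_col: str = "sofa",
    variant: str | None = None,
) -> pd.DataFrame:
    """Spearman rho and p of each feature against the SOFA score."""
    df = table if variant is None else table[table["variant"] == variant]
    rows = []
    for feat in features:
        rho, p = spearman_vs_severity(df[feat], df[sofa_col])
        rows.append({"feature": feat, "rho": rho, "p": p})
    return pd.DataFrame(rows)
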