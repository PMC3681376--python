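"""Dissimilarity-based two-cluster analysis of the feature table.

Pairwise Euclidean distances over a chosen feature subset form a
dissimilarity matrix; k-means with k = 2 partitions the subjects, and the
partition is scored both geometrically (intraclass/interclass distances and
a clustering cost) and against the clinically meaningful binary split
SIRS (noninfected) versus sepsis/septic shock (infected).

The geometric measures are not uniquely standardized in the field; the
definitions used here are recorded in the output metadata:

- ``c_k``: mean pairwise distance within cluster k,
- ``d_kl``: mean distance from members of cluster k to the centroid of
  cluster l (computed from the distance matrix via the Euclidean
  point-to-centroid identity),
- ``cost = (c1 + c2) / (d12 + d21)`` -- lower is better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

INFECTED_GROUPS = frozenset({"sepsis", "septic_shock"})

#: Feature subsets studied for cluster structure (ultradian/metabolic
#: entropy groupings, MSE features, raw temperature statistics, energies).
PRESET_SUBSETS: dict[str, list[str]] = {
    "DWT high ultradian entropy (WEn5-6)": ["WEn_s5", "WEn_s6"],
    "DWT low ultradian entropy (WEn7-8)": ["WEn_s7", "WEn_s8"],
    "DWT neurogenic and metabolic entropy (WEn1-2-3)": ["WEn_s1", "WEn_s2", "WEn_s3"],
    "CWT entropy neuro meta": ["CWTentro1", "CWTentro2"],
    "CWT entropies": ["CWTentro1", "CWTentro2", "CWTentro3", "CWTentro4"],
    "CWT entro ultradian": ["CWTentro3", "CWTentro4"],
    "CWT entro all and neurogenic": ["CWTentro", "CWTentro1"],
    "SampEn and sumEn": ["SampEn", "sumEn"],
    "T mean and SD": ["T_mean", "T_sd"],
    "CWT energy": ["CWTen1", "CWTen2", "CWTen3", "CWTen4"],
}


@dataclass
class DistanceMatrix:
    """Symmetric Euclidean dissimilarity matrix over a feature subset."""

    matrix: np.ndarray
    subject_ids: list
    subset_name: str = ""

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.subject_ids, columns=self.subject_ids)


def pairwise_distance_matrix(
    table: pd.DataFrame,
    subset: list[str],
    standardize: bool = False,
    id_col: str = "subject_id",
) -> DistanceMatrix:
    """Standard Euclidean distances over the subset columns.

    Features enter in raw units by default; ``standardize=True`` z-scores
    each column first.
    """
    if len(subset) == 0:
        raise ValueError("feature subset is empty")
    missing = [c for c in subset if c not in table.columns]
    if missing:
        raise ValueError(f"subset columns not in table: {missing}")
    X = table[list(subset)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature subset contains missing values")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    ids = list(table[id_col]) if id_col in table.columns else list(range(len(table)))
    return DistanceMatrix(
        matrix=squareform(pdist(X, metric="euclidean")),
        subject_ids=ids,
        subset_name="+".join(subset),
    )


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Cluster 0 is the larger cluster; ties go to the cluster containing the
    lowest subject index."""
    n1 = int((labels == 0).sum())
    n2 = int((labels == 1).sum())
    if n2 > n1 or (n2 == n1 and labels[0] == 1):
        labels = 1 - labels
    return labels


def kmeans_two(
    table: pd.DataFrame,
    subset: list[str],
    seed: int = 0,
    n_restarts: int = 50,
    standardize: bool = False,
) -> np.ndarray:
    """Two-cluster k-means assignment over a feature subset.

    Best-inertia solution over ``n_restarts`` seeded initializations; labels
    are canonicalized (0 = larger cluster) for reproducibility.
    """
    if len(table) < 4:
        raise ValueError("k-means needs at least 4 observations")
    X = table[list(subset)].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    if np.allclose(X, X[0]):
        warnings.warn("all observations identical; returning a single cluster")
        return np.zeros(len(X), dtype=int)
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    return _canonicalize(km.fit_predict(X))


@dataclass
class ClusterEvaluation:
    """Geometric quality and class agreement of a two-cluster partition."""

    n1: int
    n2: int
    c1: float
    c2: float
    d12: float
    d21: float
    cost: float
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    subset_name: str = ""
    definitions: str = (
        "c_k: mean within-cluster pairwise distance; "
        "d_kl: mean distance from cluster k members to cluster l centroid; "
        "cost=(c1+c2)/(d12+d21)"
    )

    def as_row(self) -> dict:
        return {
            "subset": self.subset_name,
            "n1": self.n1, "n2": self.n2,
            "c1": self.c1, "c2": self.c2,
            "d12": self.d12, "d21": self.d21,
            "cost": self.cost,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def _mean_within(d: np.ndarray, idx: np.ndarray) -> float:
    if len(idx) < 2:
        warnings.warn("singleton cluster: intraclass distance defined as 0")
        return 0.0
    sub = d[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def _mean_to_centroid(d: np.ndarray, from_idx: np.ndarray, to_idx: np.ndarray) -> float:
    """Mean distance from each ``from`` point to the centroid of the ``to``
    cluster, using only the Euclidean distance matrix.

    For Euclidean data, ``|p - centroid(C)|^2 = mean_q d(p, q)^2 -
    mean_{q,q'} d(q, q')^2 / 2`` over q, q' in C.
    """
    d2 = d**2
    within = d2[np.ix_(to_idx, to_idx)].mean() / 2.0
    vals = d2[np.ix_(from_idx, to_idx)].mean(axis=1) - within
    return float(np.sqrt(np.clip(vals, 0.0, None)).mean())


def cluster_quality(assignment: np.ndarray, dmatrix: DistanceMatrix) -> ClusterEvaluation:
    """Intraclass/interclass distances and clustering cost of a partition."""
    assignment = np.asarray(assignment)
    idx1 = np.flatnonzero(assignment == 0)
    idx2 = np.flatnonzero(assignment == 1)
    if len(idx1) == 0 or len(idx2) == 0:
        raise ValueError("both clusters must be non-empty")
    d = dmatrix.matrix
    c1 = _mean_within(d, idx1)
    c2 = _mean_within(d, idx2)
    d12 = _mean_to_centroid(d, idx1, idx2)
    d21 = _mean_to_centroid(d, idx2, idx1)
    denom = d12 + d21
    cost = (c1 + c2) / denom if denom > 0 else np.inf
    return ClusterEvaluation(
        n1=len(idx1), n2=len(idx2), c1=c1, c2=c2, d12=d12, d21=d21,
        cost=float(cost), subset_name=dmatrix.subset_name,
    )


def cluster_class_agreement(
    assignment: np.ndarray, groups, positive_groups=INFECTED_GROUPS
) -> tuple[float, float, float]:
    """Sensitivity, specificity, accuracy of a two-cluster partition against
    the infected (sepsis/septic shock) versus SIRS split.

    Each cluster is mapped to the class holding its majority (ties favor the
    positive class); positives are the infected subjects.
    """
    assignment = np.asarray(assignment)
    y = np.asarray([g in positive_groups for g in groups], dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    pred = np.zeros(len(y), dtype=bool)
    for k in np.unique(assignment):
        members = assignment == k
        n_pos = int(y[members].sum())
        pred[members] = n_pos >= int((~y)[members].sum())  # tie -> positive
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    sensitivity = tp / int(y.sum())
    specificity = tn / int((~y).sum())
    accuracy = (tp + tn) / len(y)
    return float(sensitivity), float(specificity), float(accuracy)


def evaluate_subsets(
    table: pd.DataFrame,
    subsets: dict[str, list[str]] | None = None,
    variant: str = "sign_mdetr",
    seed: int = 0,
    n_restarts: int = 50,
    standardize: bool = False,
) -> pd.DataFrame:
    """Cluster-evaluation table over the preset (or given) feature subsets,
    sorted by clustering cost."""
    subsets = subsets or PRESET_SUBSETS
    df = table[table["variant"] == variant] if "variant" in table.columns else table
    rows = []
    for name, cols in subsets.items():
        dmat = pairwise_distance_matrix(df, cols, standardize=standardize)
        labels = kmeans_two(df, cols, seed=seed, n_restarts=n_restarts,
                            standardize=standardize)
        ev = cluster_quality(labels, dmat)
        ev.subset_name = name
        if "group" in df.columns:
            sens, spec, acc = cluster_class_agreement(labels, df["group"])
            ev.sensitivity, ev.specificity, ev.accuracy = sens, spec, acc
        rows.append(ev.as_row())
    return pd.DataFrame(rows).sort_values("cost").reset_index(drop=True)


class TwoClusterKMeans(BaseEstimator, ClusterMixin):
    """scikit-learn wrapper: canonicalized two-cluster k-means with the
    geometric evaluation attached after :meth:`fit`."""

    def __init__(self, n_restarts: int = 50, random_state: int = 0,
                 standardize: bool = False):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.standardize = standardize

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        self.labels_ = kmeans_two(
            df, list(df.columns), seed=self.random_state,
            n_restarts=self.n_restarts, standardize=self.standardize,
        )
        dmat = pairwise_distance_matrix(df, list(df.columns),
                                        standardize=self.standardize, id_col="__none__")
        if len(np.unique(self.labels_)) == 2:
            self.evaluation_ = cluster_quality(self.labels_, dmat)
        else:
            self.evaluation_ = None
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
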