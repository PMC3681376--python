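"""Wrapper feature selection with LDA and leave-one-out evaluation.

A heuristic wrapper repeatedly draws random feature subsets (four features
at a time by default), scores each subset by the leave-one-out
cross-validated balanced accuracy -- the mean of sensitivity and specificity,
chosen over raw accuracy because the group sizes are unbalanced -- of a
linear discriminant classifier, and counts how often each feature appears in
a subset that reaches the success threshold (80% balanced accuracy by
default).  The most frequently appearing features form the selected set
("randset"); the reported model re-evaluates the top features at every size
up to the search size and keeps the best.

Classification is strictly pairwise binary (SIRS vs sepsis, SIRS vs septic
shock, sepsis vs septic shock); for pairs involving SIRS the positive class
is SIRS, otherwise the more severe group.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import feature_columns

GROUP_ORDER = ("SIRS", "sepsis", "septic_shock")


# ------------------------------------------------------------------- LDA

class LinearDiscriminant(BaseEstimator, ClassifierMixin):
    """Binary linear discriminant analysis from class means and a pooled
    covariance, with a small ridge term for the singular small-sample case.

    The pooled covariance is regularized as ``S + lam * trace(S)/p * I``
    (``lam = 1e-3``), which leaves well-conditioned problems essentially
    untouched while keeping the discriminant defined when ``n < p + 2``.
    Class priors are empirical.
    """

    def __init__(self, ridge: float = 1e-3):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"exactly 2 classes required, got {len(self.classes_)}")
        n, p = X.shape
        means, priors = [], []
        pooled = np.zeros((p, p))
        for c in self.classes_:
            xc = X[y == c]
            if len(xc) < 1:
                raise ValueError(f"class {c!r} has no samples")
            means.append(xc.mean(axis=0))
            priors.append(len(xc) / n)
            if len(xc) > 1:
                pooled += (len(xc) - 1) * np.cov(xc, rowvar=False).reshape(p, p)
        dof = max(n - 2, 1)
        pooled /= dof
        tr = np.trace(pooled)
        lam = self.ridge * (tr / p if tr > 0 else 1.0)
        pooled += lam * np.eye(p)
        self.means_ = np.vstack(means)
        self.priors_ = np.asarray(priors)
        w = np.linalg.solve(pooled, (self.means_[1] - self.means_[0]))
        self.coef_ = w
        self.intercept_ = (
            -0.5 * (self.means_[1] + self.means_[0]) @ w
            + np.log(self.priors_[1] / self.priors_[0])
        )
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_ + self.intercept_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def lda_fit(X, y) -> LinearDiscriminant:
    """Fit a binary linear discriminant (module-level convenience)."""
    return LinearDiscriminant().fit(X, y)


# ----------------------------------------------------------------- LOOCV

@dataclass
class ClassificationResult:
    """Pooled leave-one-out confusion metrics for one feature set."""

    feature_set: list[str]
    positive_label: object
    accuracy: float
    sensitivity: float
    specificity: float
    predictions: np.ndarray = field(repr=False, default=None)
    y_true: np.ndarray = field(repr=False, default=None)
    n_failed_folds: int = 0
    pair: str = ""
    variant: str = ""

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)


def confusion_metrics(y_true, y_pred, positive_label) -> tuple[float, float, float]:
    """Pooled (sensitivity, specificity, accuracy) of binary predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive_label
    tp = int(((y_pred == positive_label) & pos).sum())
    tn = int(((y_pred != positive_label) & ~pos).sum())
    sens = tp / int(pos.sum()) if pos.any() else float("nan")
    spec = tn / int((~pos).sum()) if (~pos).any() else float("nan")
    acc = (tp + tn) / len(y_true) if len(y_true) else float("nan")
    return float(sens), float(spec), float(acc)


def loocv_evaluate(X, y, positive_label, feature_set: list[str] | None = None) -> ClassificationResult:
    """Leave-one-out LDA evaluation with pooled confusion counts.

    Each sample is predicted by a model trained on all others.  Folds whose
    training set degenerates to a single class are recorded as failed and
    excluded from the confusion counts.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    n = len(y)
    if n < 4:
        raise ValueError("leave-one-out evaluation needs at least 4 samples")
    preds = np.empty(n, dtype=object)
    failed = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            preds[i] = None
            failed += 1
            continue
        model = LinearDiscriminant().fit(X[mask], y[mask])
        preds[i] = model.predict(X[i : i + 1])[0]
    ok = np.array([p is not None for p in preds])
    yp = preds[ok]
    yt = y[ok]
    sens, spec, acc = confusion_metrics(yt, yp, positive_label)
    return ClassificationResult(
        feature_set=list(feature_set) if feature_set is not None else [],
        positive_label=positive_label,
        accuracy=float(acc), sensitivity=float(sens), specificity=float(spec),
        predictions=yp, y_true=yt, n_failed_folds=failed,
    )


# --------------------------------------------------------------- wrapper

@dataclass
class WrapperConfig:
    """Random-subset wrapper settings."""

    subset_size: int = 4
    n_iterations: int = 10000
    success_threshold: float = 0.80
    n_top: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")
        if not 0.5 < self.success_threshold <= 1.0:
            # a threshold above 1 is allowed only as the degenerate
            # "no subset can succeed" case used in testing
            if self.success_threshold <= 0.5:
                raise ValueError("success_threshold must exceed 0.5")


@dataclass
class WrapperResult:
    """Feature significance counts and the selected feature set."""

    significance_index: pd.Series
    randset: list[str]
    successful_subsets: list[tuple[tuple[str, ...], float]]
    n_iterations: int

    @property
    def n_successful(self) -> int:
        return len(self.successful_subsets)


def wrapper_select(
    table_or_X, y=None, config: WrapperConfig | None = None,
    feature_pool: list[str] | None = None, positive_label=None,
) -> WrapperResult:
    """Random-subset wrapper feature selection.

    ``n_iterations`` subsets of ``subset_size`` features are drawn uniformly
    (without replacement within a subset); each is scored by LOOCV balanced
    accuracy and logged as successful when the score reaches the threshold.
    The significance index counts each feature's appearances in successful
    subsets; the selected set ("randset") is the top ``n_top`` features by
    that index, ties broken by feature name.
    """
    config = config or WrapperConfig()
    if isinstance(table_or_X, pd.DataFrame):
        pool = feature_pool if feature_pool is not None else list(table_or_X.columns)
        X = table_or_X[pool].to_numpy(dtype=float)
    else:
        X = np.asarray(table_or_X, dtype=float)
        pool = feature_pool if feature_pool is not None else [f"f{i}" for i in range(X.shape[1])]
    if len(pool) == 0:
        raise ValueError("feature pool is empty")
    if config.subset_size > len(pool):
        raise ValueError("subset_size exceeds the feature pool size")
    y = np.asarray(y)
    if positive_label is None:
        positive_label = np.unique(y)[0]
    rng = np.random.default_rng(config.seed)
    counts = pd.Series(0, index=pool, dtype=int)
    successes: list[tuple[tuple[str, ...], float]] = []
    for _ in range(config.n_iterations):
        idx = rng.choice(len(pool), size=config.subset_size, replace=False)
        res = loocv_evaluate(X[:, idx], y, positive_label)
        score = res.balanced_accuracy
        if score >= config.success_threshold:
            names = tuple(pool[i] for i in sorted(idx))
            successes.append((names, score))
            for nm in names:
                counts[nm] += 1
    order = sorted(pool, key=lambda nm: (-counts[nm], nm))
    randset = [nm for nm in order[: config.n_top] if counts[nm] > 0]
    return WrapperResult(
        significance_index=counts, randset=randset,
        successful_subsets=successes, n_iterations=config.n_iterations,
    )


class WrapperLDAClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn estimator: wrapper feature selection followed by LDA.

    ``fit`` runs the random-subset search on the training data, stores the
    per-feature significance index and the selected feature subset, and fits
    the final discriminant on those features.  Accepts DataFrames (named
    features) or plain arrays.
    """

    def __init__(self, subset_size: int = 4, n_iterations: int = 1000,
                 success_threshold: float = 0.80, n_top: int = 4,
                 random_state: int = 0):
        self.subset_size = subset_size
        self.n_iterations = n_iterations
        self.success_threshold = success_threshold
        self.n_top = n_top
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"f{i}" for i in range(Xv.shape[1])]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        cfg = WrapperConfig(
            subset_size=min(self.subset_size, Xv.shape[1]),
            n_iterations=self.n_iterations,
            success_threshold=self.success_threshold,
            n_top=self.n_top, seed=self.random_state,
        )
        result = wrapper_select(Xv, y, cfg, feature_pool=names,
                                positive_label=self.classes_[0])
        self.wrapper_result_ = result
        self.significance_index_ = result.significance_index
        selected = result.randset or names[: cfg.subset_size]
        self.selected_features_ = selected
        self._selected_idx = [names.index(nm) for nm in selected]
        self.model_ = LinearDiscriminant().fit(Xv[:, self._selected_idx], y)
        return self

    def _subset(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.selected_features_].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)[:, self._selected_idx]

    def predict(self, X):
        return self.model_.predict(self._subset(X))

    def decision_function(self, X):
        return self.model_.decision_function(self._subset(X))


# ------------------------------------------------------ pairwise reporting

def default_feature_pool(table: pd.DataFrame) -> list[str]:
    """The candidate features for selection: all feature columns except the
    normalized/raw duplicates of the entropy features."""
    return [
        c for c in feature_columns(table)
        if "_norm_" not in c and not c.endswith("_raw")
    ]


def positive_label_for_pair(a: str, b: str) -> str:
    """SIRS is the positive class in pairs that contain it; otherwise the
    more severe group."""
    if "SIRS" in (a, b):
        return "SIRS"
    order = {g: i for i, g in enumerate(GROUP_ORDER)}
    return max((a, b), key=lambda g: order.get(g, -1))


def pairwise_classify(
    table: pd.DataFrame,
    config: WrapperConfig | None = None,
    variants: tuple[str, ...] = ("sign_m", "sign_mdetr"),
    feature_pool: list[str] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Wrapper selection + LOOCV LDA for every group pair and signal variant.

    Returns one row per pair x variant with the selected feature set and its
    LOOCV accuracy, sensitivity and specificity.  The reported set is the
    top-significance features re-evaluated at sizes 1..subset_size, keeping
    the best balanced accuracy.
    """
    config = config or WrapperConfig()
    groups = [g for g in GROUP_ORDER if g in set(table[group_col])]
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    rows = []
    for variant in variants:
        df = table[table["variant"] == variant] if "variant" in table.columns else table
        pool = feature_pool if feature_pool is not None else default_feature_pool(df)
        for a, b in itertools.combinations(groups, 2):
            sub = df[df[group_col].isin([a, b])]
            counts = sub[group_col].value_counts()
            if counts.min() < 2:
                warnings.warn(f"pair {a} vs {b}: a group has <2 subjects; skipped")
                continue
            if counts.min() < 3:
                warnings.warn(f"pair {a} vs {b}: a group has <3 subjects")
            y = sub[group_col].to_numpy()
            pos = positive_label_for_pair(a, b)
            wres = wrapper_select(sub, y, config, feature_pool=pool,
                                  positive_label=pos)
            candidates = wres.randset or pool[: config.subset_size]
            best: ClassificationResult | None = None
            for k in range(1, len(candidates) + 1):
                feats = candidates[:k]
                res = loocv_evaluate(sub[feats], y, pos, feature_set=feats)
                if best is None or res.balanced_accuracy > best.balanced_accuracy:
                    best = res
            best.pair = f"{a} vs {b}"
            best.variant = variant
            rows.append(
                {
                    "pair": best.pair,
                    "variant": variant,
                    "features": ", ".join(best.feature_set),
                    "accuracy": best.accuracy,
                    "sensitivity": best.sensitivity,
                    "specificity": best.specificity,
                    "balanced_accuracy": best.balanced_accuracy,
                    "n_successful_subsets": wres.n_successful,
                }
            )
    return pd.DataFrame(rows)
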