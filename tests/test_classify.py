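"""LDA, leave-one-out evaluation, and wrapper feature selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from thermocomplexity.classify import (
    LinearDiscriminant,
    WrapperConfig,
    WrapperLDAClassifier,
    confusion_metrics,
    loocv_evaluate,
    pairwise_classify,
    positive_label_for_pair,
    wrapper_select,
)


def blobs(rng, n=10, sep=6.0, p=2):
    X = np.vstack([rng.normal(0, 1, size=(n, p)), rng.normal(sep, 1, size=(n, p))])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestLinearDiscriminant:
    def test_symmetric_one_dimensional_boundary_at_zero(self, rng):
        x = np.concatenate([rng.normal(-1, 1, 200), rng.normal(1, 1, 200)])
        y = np.array(["lo"] * 200 + ["hi"] * 200)
        model = LinearDiscriminant().fit(x[:, None], y)
        # equal priors and symmetric means: the decision boundary sits near 0
        boundary = -model.intercept_ / model.coef_[0]
        assert abs(boundary) < 0.15

    def test_class_swap_flips_predictions(self, rng):
        X, y = blobs(rng, sep=3.0)
        m1 = LinearDiscriminant().fit(X, y)
        swapped = np.where(y == "a", "b", "a")
        m2 = LinearDiscriminant().fit(X, swapped)
        p1 = m1.predict(X)
        p2 = m2.predict(X)
        assert np.all((p1 == "a") == (p2 == "b"))

    def test_separable_blobs_training_accuracy_one(self, rng):
        X, y = blobs(rng)
        model = LinearDiscriminant().fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_singular_small_sample_still_fits(self, rng):
        # n < p + 2: pooled covariance is singular without regularization
        X = rng.normal(size=(4, 6))
        y = np.array(["a", "a", "b", "b"])
        model = LinearDiscriminant().fit(X, y)
        assert np.isfinite(model.decision_function(X)).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            LinearDiscriminant().fit(np.zeros((3, 2)), ["a", "a", "a"])


class TestConfusionAndLOOCV:
    def test_study_sized_confusion_reconstructions(self):
        """Reconstructing pooled metrics from group sizes and printed
        sensitivity/specificity: 5+10 with 5/5 and 9/10 correct gives
        93.33% accuracy; 5+7 with 4/5 and 7/7 gives 91.67%."""
        y = np.array(["SIRS"] * 5 + ["sepsis"] * 10)
        pred = np.array(["SIRS"] * 5 + ["sepsis"] * 9 + ["SIRS"])
        sens, spec, acc = confusion_metrics(y, pred, positive_label="SIRS")
        assert acc * 100 == pytest.approx(93.33, abs=0.01)
        assert (sens, spec) == (1.0, 0.9)

        y = np.array(["SIRS"] * 5 + ["septic_shock"] * 7)
        pred = np.array(["SIRS"] * 4 + ["septic_shock"] + ["septic_shock"] * 7)
        sens, spec, acc = confusion_metrics(y, pred, positive_label="SIRS")
        assert acc * 100 == pytest.approx(91.67, abs=0.01)
        assert (sens, spec) == (0.8, 1.0)

    def test_perfect_classifier_on_separable_data(self, rng):
        X, y = blobs(rng)
        res = loocv_evaluate(X, y, positive_label="a")
        assert (res.accuracy, res.sensitivity, res.specificity) == (1.0, 1.0, 1.0)
        assert res.balanced_accuracy == 1.0

    def test_fold_count_and_confusion_consistency(self, rng):
        X, y = blobs(rng, n=6, sep=1.0)
        res = loocv_evaluate(X, y, positive_label="a")
        assert len(res.predictions) == 12
        correct = (res.predictions == res.y_true).mean()
        assert res.accuracy == pytest.approx(correct)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            loocv_evaluate(np.zeros((3, 1)), ["a", "a", "b"], positive_label="a")


class TestWrapper:
    def _table(self, rng, n=12):
        """One perfectly separating feature among noise features."""
        y = np.array(["a"] * n + ["b"] * n)
        X = pd.DataFrame(
            {
                "informative": np.concatenate([rng.normal(0, 0.3, n),
                                               rng.normal(5, 0.3, n)]),
                **{f"noise{i}": rng.normal(size=2 * n) for i in range(5)},
            }
        )
        return X, y

    def test_perfect_feature_gets_maximal_significance(self, rng):
        X, y = self._table(rng)
        cfg = WrapperConfig(subset_size=3, n_iterations=150, seed=0)
        res = wrapper_select(X, y, cfg, positive_label="a")
        counts = res.significance_index
        assert counts["informative"] == counts.max()
        assert "informative" in res.randset

    def test_unattainable_threshold_gives_empty_randset(self, rng):
        X, y = self._table(rng)
        cfg = WrapperConfig(subset_size=3, n_iterations=50, seed=0,
                            success_threshold=1.01)
        res = wrapper_select(X, y, cfg, positive_label="a")
        assert res.n_successful == 0
        assert res.randset == []
        assert (res.significance_index == 0).all()

    def test_deterministic_given_seed(self, rng):
        X, y = self._table(rng)
        cfg = WrapperConfig(subset_size=3, n_iterations=80, seed=7)
        r1 = wrapper_select(X, y, cfg, positive_label="a")
        r2 = wrapper_select(X, y, cfg, positive_label="a")
        assert r1.randset == r2.randset
        assert r1.significance_index.equals(r2.significance_index)
        assert r1.successful_subsets == r2.successful_subsets

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            wrapper_select(pd.DataFrame(index=[0, 1]), ["a", "b"],
                           WrapperConfig(subset_size=1, n_iterations=5))


class TestWrapperLDAClassifier:
    def test_fit_predict_selects_informative_feature(self, rng):
        y = np.array(["a"] * 10 + ["b"] * 10)
        X = pd.DataFrame({
            "good": np.concatenate([rng.normal(0, 0.3, 10), rng.normal(4, 0.3, 10)]),
            "junk": rng.normal(size=20),
        })
        clf = WrapperLDAClassifier(subset_size=2, n_iterations=40, random_state=0)
        clf.fit(X, y)
        assert "good" in clf.selected_features_
        assert np.mean(clf.predict(X) == y) >= 0.9

    def test_sklearn_protocol(self):
        clf = WrapperLDAClassifier(n_iterations=10)
        params = clf.get_params()
        assert params["n_iterations"] == 10
        assert clone(clf).get_params() == params


class TestPairwiseClassification:
    def test_positive_label_convention(self):
        assert positive_label_for_pair("SIRS", "sepsis") == "SIRS"
        assert positive_label_for_pair("septic_shock", "SIRS") == "SIRS"
        assert positive_label_for_pair("sepsis", "septic_shock") == "septic_shock"

    def _synthetic_feature_table(self, rng):
        """Direct feature-table construction (no signal simulation): three
        groups separated along one feature, both variants present."""
        rows = []
        shift = {"SIRS": 0.0, "sepsis": 3.0, "septic_shock": 6.0}
        for variant in ("sign_m", "sign_mdetr"):
            for g, mu in shift.items():
                for k in range(6):
                    rows.append({
                        "subject_id": f"{g}{k}", "group": g, "sofa": 10,
                        "variant": variant,
                        "featA": rng.normal(mu, 0.4),
                        "featB": rng.normal(0, 1),
                    })
        return pd.DataFrame(rows)

    def test_three_pairs_times_two_variants(self, rng):
        table = self._synthetic_feature_table(rng)
        cfg = WrapperConfig(subset_size=2, n_iterations=30, seed=0)
        out = pairwise_classify(table, cfg, feature_pool=["featA", "featB"])
        assert len(out) == 6
        assert set(out["pair"]) == {"SIRS vs sepsis", "SIRS vs septic_shock",
                                    "sepsis vs septic_shock"}
        assert out["balanced_accuracy"].min() >= 0.8

    def test_single_feature_subsets_reproduce_univariate_models(self, rng):
        table = self._synthetic_feature_table(rng)
        cfg = WrapperConfig(subset_size=1, n_iterations=30, seed=0, n_top=1)
        out = pairwise_classify(table, cfg, feature_pool=["featA", "featB"])
        assert set(out["features"]) == {"featA"}
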