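import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import cereconn as cc
from cereconn.discrimination import NoModelError
from cereconn.types import ValidationError


def contrast_frame(rows):
    base = {"condition": "1-back", "contrast": "SCZ:CON"}
    return pd.DataFrame([{**base, **r} for r in rows])


class TestFitComposite:
    def test_two_feature_model_weights(self):
        df = contrast_frame(
            [
                {"feature": "CER-SM", "q": 0.0015, "d": -1.547},
                {"feature": "CER-CO", "q": 0.0298, "d": -1.155},
                {"feature": "DMN-FP", "q": 0.40, "d": 0.2},
                {"feature": "intra_CER", "q": 0.001, "d": -2.0},  # wrong class
            ]
        )
        model = cc.fit_composite(df)
        assert model.features == ["CER-SM", "CER-CO"]
        assert np.allclose(model.weights, [1.547, 1.155])
        feats = pd.DataFrame({"CER-SM": [1.0, 0.0], "CER-CO": [0.0, 1.0]})
        s = cc.score(model, feats)
        assert np.allclose(s, [1.547, 1.155])

    def test_single_feature_is_identity_up_to_weight(self):
        df = contrast_frame([{"feature": "CER-SM", "q": 0.01, "d": 1.0}])
        model = cc.fit_composite(df)
        feats = pd.DataFrame({"CER-SM": [0.3, -0.2, 1.5]})
        assert np.allclose(cc.score(model, feats), feats["CER-SM"])

    def test_nothing_significant_raises(self):
        df = contrast_frame([{"feature": "CER-SM", "q": 0.2, "d": 1.0}])
        with pytest.raises(NoModelError):
            cc.fit_composite(df)


class TestScore:
    def test_zero_features_zero_score(self):
        model = cc.CompositeModel(["a", "b"], np.array([2.0, 3.0]), "SCZ:CON", "1-back", 0.05)
        feats = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 1.0]})
        assert np.allclose(cc.score(model, feats), [0.0, 5.0])

    def test_weight_scaling_leaves_auc_unchanged(self, rng):
        feats = pd.DataFrame({"a": rng.standard_normal(30), "b": rng.standard_normal(30)})
        labels = (np.arange(30) < 15).astype(int)
        m1 = cc.CompositeModel(["a", "b"], np.array([1.0, 2.0]), "c", "1-back", 0.05)
        m2 = cc.CompositeModel(["a", "b"], np.array([2.0, 4.0]), "c", "1-back", 0.05)
        s1, s2 = cc.score(m1, feats), cc.score(m2, feats)
        assert np.allclose(s2, 2 * s1)
        assert cc.rank_auc(s1.to_numpy(), labels) == cc.rank_auc(s2.to_numpy(), labels)

    def test_missing_feature_rejected(self):
        model = cc.CompositeModel(["zz"], np.array([1.0]), "c", "1-back", 0.05)
        with pytest.raises(ValidationError, match="zz"):
            cc.score(model, pd.DataFrame({"a": [1.0]}))


class TestRankAuc:
    def test_perfect_separation(self):
        assert cc.rank_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_three_of_four_concordant(self):
        assert cc.rank_auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75

    def test_all_ties_midrank(self):
        assert cc.rank_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_equals_trapezoid_of_empirical_curve(self, rng):
        """Rank estimator == trapezoidal area under the ROC curve, 200 instances."""
        for _ in range(200):
            n = int(rng.integers(6, 40))
            scores = rng.standard_normal(n)
            if rng.random() < 0.3:  # induce ties sometimes
                scores = np.round(scores, 1)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            res = cc.roc(scores, labels, n_boot=0)
            trap = float(np.trapezoid(res.tpr, res.fpr))
            assert abs(res.auc - trap) < 1e-12

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, 40)
        base = cc.rank_auc(scores, labels)
        for f in (np.exp, lambda x: x**3 + x, lambda x: np.arctan(x)):
            assert np.isclose(cc.rank_auc(f(scores), labels), base)


class TestRoc:
    def test_orientation_flag(self, rng):
        scores = np.r_[rng.standard_normal(20) + 2, rng.standard_normal(20)]
        labels = np.r_[np.zeros(20, int), np.ones(20, int)]  # positives score LOW
        res = cc.roc(scores, labels, n_boot=0)
        assert res.flipped and res.auc > 0.5

    def test_bootstrap_ci_contains_point_estimate(self, rng):
        hits = 0
        for _ in range(100):
            n = int(rng.integers(12, 30))
            scores = rng.standard_normal(n)
            labels = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
            res = cc.roc(scores, labels, n_boot=300, seed=int(rng.integers(2**31)))
            if res.auc_ci[0] - 1e-12 <= res.auc <= res.auc_ci[1] + 1e-12:
                hits += 1
        assert hits >= 99

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            cc.roc(np.arange(5.0), np.ones(5, int), n_boot=0)


class TestYouden:
    def test_perfect_separation(self):
        res = cc.roc([1, 2, 10, 11], [0, 0, 1, 1], n_boot=0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_matches_exhaustive_sweep(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 1, 0, 1])
        res = cc.roc(scores, labels, n_boot=0)
        # brute force over all distinct thresholds
        best = []
        for t in np.r_[scores, scores.max() + 1]:
            pred = scores >= t
            sens = (pred & (labels == 1)).sum() / 2
            spec = (~pred & (labels == 0)).sum() / 2
            best.append((sens + spec - 1, spec, sens))
        jmax = max(b[0] for b in best)
        assert np.isclose(res.sensitivity + res.specificity - 1, jmax)
        # tie broken toward the higher specificity among J-maximizers
        best_spec = max(b[1] for b in best if np.isclose(b[0], jmax))
        assert np.isclose(res.specificity, best_spec)

    def test_symmetric_overlap_balances_sens_spec(self, rng):
        scores = np.r_[rng.standard_normal(2000) + 1, rng.standard_normal(2000)]
        labels = np.r_[np.ones(2000, int), np.zeros(2000, int)]
        res = cc.roc(scores, labels, n_boot=0)
        assert abs(res.sensitivity - res.specificity) < 0.1


class TestCompositeAucClosedForm:
    def test_simulation_matches_gaussian_formula(self, rng):
        """Planted-weight composite AUC matches Phi(w.D / sqrt(2 w'Sw))."""
        w = np.array([1.547, 1.155])
        rho = 0.25
        sigma = np.array([[1, rho], [rho, 1]])
        chol = np.linalg.cholesky(sigma)
        expected = norm.cdf(w @ w / (np.sqrt(2) * np.sqrt(w @ sigma @ w)))
        aucs = []
        for _ in range(400):
            pat = rng.standard_normal((23, 2)) @ chol.T - w
            con = rng.standard_normal((20, 2)) @ chol.T
            s = np.r_[pat @ w, con @ w]
            lab = np.r_[np.ones(23, int), np.zeros(20, int)]
            a = cc.rank_auc(s, lab)
            aucs.append(max(a, 1 - a))
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - expected) < 4 * se + 0.005


class TestMisclassificationProfile:
    def _setup(self):
        # 6 patients (label 1), 3 controls; oriented scores = raw
        scores = np.array([0.02, 0.06, 0.9, 1.0, 1.1, 1.2, 0.0, 0.05, 0.15])
        labels = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0])
        res = cc.roc(scores, labels, n_boot=0)
        meta = pd.DataFrame(
            {
                "subtype": [3, 3, 1, 1, 2, 1, 1, 2, 3],
                "sans_global": [1.0, 2.0, 3.0, 4.0, 5.0, 3.5, 0, 0, 0],
            }
        )
        return scores, labels, res, meta

    def test_planted_crosstab(self):
        scores, labels, res, meta = self._setup()
        prof = cc.misclassification_profile(scores, labels, res, meta, focal_subtype=3)
        # the two low-scoring patients (subtype 3) are misclassified
        assert prof.crosstab.loc["misclassified", "focal_subtype"] == 2
        assert prof.crosstab.loc["misclassified", "other"] == 0
        assert prof.crosstab.loc["correct", "focal_subtype"] == 0
        assert prof.crosstab.loc["correct", "other"] == 4
        assert prof.fisher_p is not None

    def test_clinical_means_hand_average(self):
        scores, labels, res, meta = self._setup()
        prof = cc.misclassification_profile(
            scores, labels, res, meta, focal_subtype=3, clinical_columns=["sans_global"]
        )
        assert np.isclose(prof.clinical_means.loc["sans_global", "misclassified"], 1.5)
        assert np.isclose(prof.clinical_means.loc["sans_global", "correct"], 3.875)

    def test_zero_misclassified_reports_not_applicable(self):
        scores = np.array([1.0, 1.1, 1.2, 0.0, 0.1])
        labels = np.array([1, 1, 1, 0, 0])
        res = cc.roc(scores, labels, n_boot=0)
        meta = pd.DataFrame({"subtype": [1, 2, 1, 1, 2]})
        prof = cc.misclassification_profile(scores, labels, res, meta, focal_subtype=2)
        assert prof.fisher_p is None
        assert "not applicable" in prof.note
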