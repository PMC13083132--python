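from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

import cereconn as cc
from cereconn.clustering import _jaccard_partitions
from cereconn.types import ValidationError


def blobs(centers, n_per, sd, seed=0):
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(np.asarray(c) + sd * rng.standard_normal((n_per, len(c))))
        labels += [i + 1] * n_per
    return np.vstack(pts), np.array(labels)


class TestMinMaxNormalize:
    def test_endpoints_and_midpoint(self):
        df = pd.DataFrame(
            {"group": ["SCZ"] * 3, "saps_global": [0.0, 2.5, 5.0],
             "cog_vocabulary": [10.0, 15.0, 20.0]},
            index=pd.Index(["a", "b", "c"], name="subject_id"),
        )
        norm = cc.minmax_normalize(cc.ClinicalTable(df))
        assert np.allclose(norm.data["saps_global"], [0.0, 0.5, 1.0])
        assert np.allclose(norm.data["cog_vocabulary"], [0.0, 0.5, 1.0])
        assert norm.bounds_used["saps_global"] == (0.0, 5.0)  # theoretical
        assert norm.bounds_used["cog_vocabulary"] == (10.0, 20.0)  # observed

    def test_listwise_deletion(self):
        df = pd.DataFrame(
            {
                "group": ["SCZ"] * 4,
                "saps_global": [1.0, np.nan, 2.0, 3.0],
                "cog_vocabulary": [1.0, 2.0, np.nan, 4.0],
                "cog_digit_span": [1.0, np.nan, 2.0, 3.0],
            },
            index=pd.Index(list("abcd"), name="subject_id"),
        )
        norm = cc.minmax_normalize(cc.ClinicalTable(df))
        assert norm.dropped == ["b", "c"]  # 3 missing cells in exactly 2 rows
        assert list(norm.data.index) == ["a", "d"]
        assert not norm.data.isna().any().any()

    def test_constant_cognitive_column_rejected(self):
        df = pd.DataFrame(
            {"group": ["SCZ"] * 3, "cog_vocabulary": [2.0, 2.0, 2.0]},
            index=pd.Index(list("abc"), name="subject_id"),
        )
        with pytest.raises(ValidationError, match="cog_vocabulary"):
            cc.minmax_normalize(cc.ClinicalTable(df))


class TestPam:
    def test_two_gap_clusters(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        res = cc.pam(pts, 2)
        assert res.labels[0] == res.labels[1] != res.labels[2]
        assert res.labels[2] == res.labels[3]
        assert np.isclose(res.cost, 2.0)

    def test_k_equals_n(self):
        pts = np.arange(5.0).reshape(-1, 1)
        res = cc.pam(pts, 5)
        assert res.cost == 0.0
        assert len(set(res.labels)) == 5

    def test_duplicated_dataset_same_partition(self, rng):
        pts, _ = blobs([[0, 0], [4, 4], [8, 0]], 6, 0.3)
        res1 = cc.pam(pts, 3)
        res2 = cc.pam(np.vstack([pts, pts]), 3)
        assert adjusted_rand_score(res1.labels, res2.labels[: len(pts)]) == 1.0
        assert adjusted_rand_score(res2.labels[: len(pts)], res2.labels[len(pts):]) == 1.0

    def test_matches_exhaustive_search_small_n(self, rng):
        """BUILD+SWAP reaches the global medoid optimum for n <= 8."""
        for trial in range(40):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, n))
            pts = rng.standard_normal((n, 2))
            d = cdist(pts, pts)
            best = min(
                d[list(m)].min(axis=0).sum() for m in combinations(range(n), k)
            )
            assert np.isclose(cc.pam(pts, k).cost, best)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            cc.pam(np.zeros((3, 1)), 5)


class TestConsensus:
    def test_separated_blobs_fully_stable(self):
        pts, truth = blobs([[0, 0], [10, 10], [20, 0]], 10, 0.2)
        sol = cc.consensus_cluster(pts, 3, iterations=50, seed=0)
        defined = sol.consensus[np.isfinite(sol.consensus)]
        assert set(np.round(defined, 8)) <= {0.0, 1.0}
        assert sol.metrics["PAC"] == 0.0
        assert adjusted_rand_score(truth, sol.labels) == 1.0

    def test_noise_is_unstable(self, rng):
        # On a fixed noise dataset, subsample partitions stay partially
        # consistent (the objective is deterministic), so the ARI sits well
        # below the ~1.0 of planted structure without reaching 0.
        pts = rng.random((60, 5))
        sol = cc.consensus_cluster(pts, 3, iterations=50, seed=1)
        assert sol.metrics["PAC"] > 0.2
        assert sol.metrics["mean_pairwise_ari"] < 0.7

    def test_determinism(self, rng):
        pts = rng.random((40, 4))
        s1 = cc.consensus_cluster(pts, 3, iterations=30, seed=7)
        s2 = cc.consensus_cluster(pts, 3, iterations=30, seed=7)
        assert np.array_equal(s1.labels, s2.labels)
        assert np.allclose(s1.consensus, s2.consensus, equal_nan=True)
        assert s1.metrics == s2.metrics

    def test_consensus_matrix_invariants(self, rng):
        pts = rng.random((30, 3))
        sol = cc.consensus_cluster(pts, 2, iterations=40, seed=3)
        c = sol.consensus
        assert np.allclose(c, c.T, equal_nan=True)
        assert np.all(np.diag(c) == 1.0)
        finite = c[np.isfinite(c)]
        assert finite.min() >= 0 and finite.max() <= 1
        assert set(sol.labels) <= {1, 2}


class TestPac:
    def test_binary_consensus_zero(self):
        c = np.array([[1, 0, 1.0], [0, 1, 0], [1, 0, 1]])
        assert cc.pac(c) == 0.0

    def test_all_ambiguous_one(self):
        c = np.full((4, 4), 0.5)
        np.fill_diagonal(c, 1.0)
        assert cc.pac(c) == 1.0

    def test_direct_count(self):
        c = np.eye(4)
        vals = [0.05, 0.5, 0.95, 1.0, 0.05, 0.95]
        iu = np.triu_indices(4, 1)
        c[iu] = vals
        c = c + c.T - np.diag(np.diag(c))
        np.fill_diagonal(c, 1.0)
        assert np.isclose(cc.pac(c), 1 / 6)  # only 0.5 lies strictly inside


class TestStabilityMetrics:
    def test_two_tight_blobs_high_silhouette(self):
        pts, _ = blobs([[0, 0], [50, 50]], 12, 0.1)
        sol = cc.consensus_cluster(pts, 2, iterations=30, seed=0)
        m = cc.stability_metrics(sol, pts)
        assert m["silhouette"] > 0.9
        assert m["mean_pairwise_ari"] == 1.0
        assert m["mean_pairwise_jaccard"] == 1.0

    def test_jaccard_identical_partitions(self):
        a = np.array([1, 1, 2, 2, 3])
        assert _jaccard_partitions(a, a) == 1.0

    def test_random_labels_near_zero_ari(self, rng):
        aris = []
        for _ in range(100):
            a = rng.integers(1, 4, 40)
            b = rng.integers(1, 4, 40)
            aris.append(adjusted_rand_score(a, b))
        assert abs(np.mean(aris)) < 0.03

    def test_k1_rejected(self):
        pts = np.zeros((5, 2))
        sol = cc.ClusterSolution(1, np.ones(5, int), np.array([0]), np.eye(5))
        with pytest.raises(ValidationError):
            cc.stability_metrics(sol, pts)


class TestPermutationTest:
    def test_strong_blobs_minimal_p(self):
        pts, _ = blobs([[0, 0], [8, 8], [16, 0]], 10, 0.2)
        assert cc.permutation_test(pts, 3, B=999, seed=0) == 1 / 1000

    def test_null_calibration(self, rng):
        ps = []
        for i in range(20):
            pts = rng.random((30, 4))
            ps.append(cc.permutation_test(pts, 3, B=49, seed=i))
        assert 0.2 < np.mean(ps) < 0.8


class TestSelectK:
    def test_two_planted_blobs(self):
        pts, _ = blobs([[0, 0, 0], [5, 5, 5]], 20, 0.3)
        sel = cc.select_k(pts, range(2, 6), iterations=40, seed=0)
        assert sel.chosen_k == 2
        assert sel.stable

    def test_three_planted_subtypes(self):
        table, truth = cc.generate_clinical_table(cc.default_subtype_preset(), 98, seed=0)
        pts = cc.minmax_normalize(table).data.to_numpy(float)
        sel = cc.select_k(pts, range(2, 7), iterations=100, seed=0)
        assert sel.chosen_k == 3
        ari = adjusted_rand_score(truth.to_numpy(), sel.solutions[3].labels)
        assert ari >= 0.9

    def test_noise_flagged_or_high_pac(self, rng):
        pts = rng.random((50, 8))
        sel = cc.select_k(pts, range(2, 5), iterations=30, seed=2)
        # under pure noise every k is far less stable than planted structure
        assert sel.table["PAC"].min() > 0.05
        assert sel.stable == (sel.table["PAC"].min() <= 0.5)


class TestProfileSubtypes:
    def test_noise_free_profile_equals_centroids(self):
        preset = cc.SubtypePreset(within_subtype_sd=0.0)
        table, truth = cc.generate_clinical_table(preset, 60, seed=0)
        norm = cc.minmax_normalize(table)
        profile, comp = cc.profile_subtypes(truth.to_numpy(), norm)
        for s in (1, 2, 3):
            assert np.allclose(
                profile.loc[s].to_numpy(),
                preset.centroids.loc[s].to_numpy(), atol=1e-12,
            )
        assert np.allclose(comp.sum(axis=1), 100.0)

    def test_default_preset_subtype1_cognition_band(self):
        table, _ = cc.generate_clinical_table(cc.default_subtype_preset(), 98, seed=0)
        norm = cc.minmax_normalize(table)
        sol = cc.consensus_cluster(norm.data.to_numpy(float), 3, iterations=50, seed=0)
        profile, comp = cc.profile_subtypes(sol.labels, norm)
        # identify the control-enriched subtype by its minimal symptom burden
        s1 = profile["saps_global"].idxmin()
        cog = profile.loc[s1, ["cog_vocabulary", "cog_family_pictures_i",
                               "cog_family_pictures_ii"]]
        assert ((cog >= 0.60) & (cog <= 0.65)).all()
        assert comp.loc[s1, ["CON", "CON-SIB"]].sum() > 95
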