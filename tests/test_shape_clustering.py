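import itertools

import numpy as np
import pandas as pd
import pytest

from chromtss import shape_clustering as sc


class TestPearsonDistance:
    def test_identical_nonconstant_zero(self):
        a = np.array([1.0, 2.0, 5.0, 3.0])
        assert sc.pearson_distance(a, a) == pytest.approx(0.0)

    def test_anticorrelated_two(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert sc.pearson_distance(a, -a) == pytest.approx(2.0)

    def test_affine_invariance(self):
        a = np.array([0.5, 1.5, -2.0, 4.0, 1.0])
        assert sc.pearson_distance(a, 3 * a + 7) == pytest.approx(0.0)
        assert sc.pearson_distance(3 * a + 7, a) == pytest.approx(0.0)

    def test_constant_vector_distance_one(self):
        a = np.array([1.0, 2.0, 3.0])
        assert sc.pearson_distance(a, np.full(3, 9.0)) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sc.pearson_distance(np.zeros(3), np.zeros(4))


def _brute_force_best_2partition(x: np.ndarray) -> float:
    """Exhaustive minimum of the k=2 within-cluster 1-r objective."""
    n = len(x)
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n - 1):
        assign = np.array((0,) + bits)
        if assign.sum() in (0, n):
            continue
        obj = 0.0
        for c in (0, 1):
            members = x[assign == c]
            centroid = members.mean(axis=0)
            obj += float(
                (1 - sc.pearson_correlation_matrix(members, centroid)[:, 0]).sum()
            )
        best = min(best, obj)
    return best


class TestKmeans:
    def test_two_separated_groups_perfectly_split(self):
        rng = np.random.default_rng(1)
        up = np.linspace(0, 1, 48)
        a = up + rng.normal(0, 0.01, (10, 48))
        b = up[::-1] + rng.normal(0, 0.01, (10, 48))
        profiles = pd.DataFrame(np.vstack([a, b]))
        res = sc.kmeans_shapes(profiles, k=2, npass=20, seed=2)
        labels = res.assignments.values
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]
        assert res.objective < 0.1

    def test_k1_centroid_is_global_mean(self):
        rng = np.random.default_rng(3)
        profiles = pd.DataFrame(rng.random((7, 48)))
        res = sc.kmeans_shapes(profiles, k=1, npass=5, seed=1)
        assert np.allclose(res.subprofiles[0], profiles.values.mean(axis=0))

    def test_fewer_profiles_than_k_rejected(self):
        profiles = pd.DataFrame(np.random.default_rng(0).random((3, 48)))
        with pytest.raises(ValueError):
            sc.kmeans_shapes(profiles, k=5, npass=5, seed=1)

    def test_best_of_200_matches_exhaustive_minimum(self):
        """On tiny instances the multi-start search must find the global
        optimum over all 2-partitions."""
        rng = np.random.default_rng(42)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            x = rng.random((n, 12))
            _, _, obj = sc.kmeans_pearson(x, k=2, npass=200, seed=int(rng.integers(2**31)))
            assert obj == pytest.approx(_brute_force_best_2partition(x), abs=1e-9)

    def test_best_of_npass_not_worse_than_single_pass(self):
        rng = np.random.default_rng(5)
        x = rng.random((30, 20))
        _, _, multi = sc.kmeans_pearson(x, k=4, npass=50, seed=9)
        for s in range(5):
            _, _, single = sc.kmeans_pearson(x, k=4, npass=1, seed=s)
            assert multi <= single + 1e-9

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(6)
        x = pd.DataFrame(rng.random((25, 48)))
        a = sc.kmeans_shapes(x, k=3, npass=10, seed=4)
        b = sc.kmeans_shapes(x, k=3, npass=10, seed=4)
        assert a.assignments.equals(b.assignments)
        assert a.objective == b.objective

    def test_agrees_with_biopython_kcluster(self):
        """Independent oracle: Bio.Cluster's kcluster with correlation
        distance finds the same partition on well-separated shapes."""
        Bio_Cluster = pytest.importorskip("Bio.Cluster")
        rng = np.random.default_rng(7)
        shapes = [
            np.sin(np.linspace(0, np.pi, 48)),
            np.linspace(0, 1, 48),
            np.linspace(1, 0, 48),
        ]
        x = np.vstack(
            [s + rng.normal(0, 0.05, (8, 48)) for s in shapes for _ in [0]]
        )
        ours, _, _ = sc.kmeans_pearson(x, k=3, npass=50, seed=8)
        theirs, _, _ = Bio_Cluster.kcluster(x, nclusters=3, dist="c", npass=50)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(ours, np.asarray(theirs)) == 1.0


class TestSubprofileCorrelations:
    def test_identical_profile_scores_one(self):
        subs = np.vstack([np.linspace(0, 1, 48), np.linspace(1, 0, 48)])
        feats = sc.subprofile_correlations(subs[1], subs, raw_total=500)
        assert feats[1] == pytest.approx(1.0)

    def test_low_signal_masked_to_zero(self):
        subs = np.vstack([np.linspace(0, 1, 48)])
        feats = sc.subprofile_correlations(np.linspace(0, 1, 48), subs, raw_total=99)
        assert np.array_equal(feats, np.zeros(1))

    def test_constant_profile_gives_zeros(self):
        subs = np.vstack([np.linspace(0, 1, 48)])
        feats = sc.subprofile_correlations(np.full(48, 2.0), subs, raw_total=500)
        assert np.array_equal(feats, np.zeros(1))


class TestMetaMatrix:
    def _per_mark(self, marks, rng, ids, k=5):
        out = {}
        for m in marks:
            profiles = pd.DataFrame(rng.random((len(ids), 48)), index=ids)
            totals = pd.Series(500.0, index=ids)
            subset = sc.kmeans_shapes(profiles, m, k=k, npass=2, seed=1)
            out[m] = (profiles, totals, subset)
        return out

    def test_twelve_marks_sixty_columns(self):
        rng = np.random.default_rng(9)
        ids = [f"r{i}" for i in range(10)]
        per_mark = self._per_mark([f"m{i:02d}" for i in range(12)], rng, ids)
        mat = sc.build_meta_matrix(per_mark, ids)
        assert mat.shape == (10, 60)

    def test_eleven_marks_fiftyfive_columns(self):
        rng = np.random.default_rng(10)
        ids = [f"r{i}" for i in range(10)]
        per_mark = self._per_mark([f"m{i:02d}" for i in range(11)], rng, ids)
        assert sc.build_meta_matrix(per_mark, ids).shape == (10, 55)

    def test_missing_profiles_give_zero_row(self):
        rng = np.random.default_rng(11)
        ids = [f"r{i}" for i in range(8)]
        per_mark = self._per_mark(["mA"], rng, ids)
        mat = sc.build_meta_matrix(per_mark, ids + ["ghost"])
        assert np.array_equal(mat.loc["ghost"].values, np.zeros(5))

    def test_no_marks_rejected(self):
        with pytest.raises(ValueError):
            sc.build_meta_matrix({}, ["a"])


class TestMetacluster:
    def test_two_archetypes_fully_recovered(self):
        rng = np.random.default_rng(12)
        a = np.tile([1.0, 0.0, 0.5, -0.5], (15, 3)) + rng.normal(0, 0.02, (15, 12))
        b = np.tile([-0.5, 0.8, -0.2, 0.1], (15, 3)) + rng.normal(0, 0.02, (15, 12))
        mat = pd.DataFrame(np.vstack([a, b]), index=[f"r{i}" for i in range(30)])
        res = sc.metacluster(mat, k=2, npass=20, seed=13)
        from sklearn.metrics import adjusted_rand_score

        truth = [0] * 15 + [1] * 15
        assert adjusted_rand_score(truth, res.assignments.values) == 1.0
        assert res.sizes.sum() == 30

    def test_duplicate_rows_colocate(self):
        rng = np.random.default_rng(14)
        base = rng.random((6, 10))
        mat = pd.DataFrame(np.vstack([base, base[0]]), index=[f"r{i}" for i in range(7)])
        res = sc.metacluster(mat, k=3, npass=20, seed=15)
        assert res.assignments.iloc[0] == res.assignments.iloc[6]

    def test_too_few_rows_rejected(self):
        mat = pd.DataFrame(np.random.default_rng(0).random((5, 10)))
        with pytest.raises(ValueError):
            sc.metacluster(mat, k=10, npass=2, seed=1)
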