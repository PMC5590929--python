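"""Kabsch superposition, RMSD matrices, complete linkage and bootstrap null."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from structmap.clustering import (RmsdMatrix, bootstrap_null,
                                  complete_linkage_clusters, consensus_ss,
                                  kabsch_rmsd, pairwise_matrix)
from structmap.synthetic import generate_window_set, template_window_atoms


class TestKabsch:
    def test_identity(self, rng):
        a = rng.normal(size=(8, 3))
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        a = rng.normal(size=(8, 3)) * 3
        for i in range(10):
            rot = Rotation.random(random_state=i).as_matrix()
            b = a @ rot.T + rng.normal(size=3) * 10
            assert kabsch_rmsd(a, b) < 1e-9

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(2, 8, 3)) * 2
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a),
                                                  abs=1e-12)

    def test_reflection_not_allowed(self, rng):
        a = rng.normal(size=(8, 3)) * 3
        mirrored = a * np.array([-1.0, 1.0, 1.0])
        # chiral point sets: the mirror image is not superposable
        assert kabsch_rmsd(a, mirrored) > 0.1

    def test_collinear_points_still_defined(self):
        a = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])
        b = np.column_stack([np.zeros(8), np.arange(8.0), np.zeros(8)])
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            kabsch_rmsd(rng.normal(size=(8, 3)), rng.normal(size=(7, 3)))


class TestPairwiseMatrix:
    def test_pair_count_and_symmetry(self, rng):
        coords = rng.normal(size=(12, 8, 3))
        m = pairwise_matrix(list(range(12)), coords)
        assert m.values.shape == (12, 12)
        assert np.allclose(m.values, m.values.T)
        assert np.count_nonzero(np.triu(m.values, k=1)) == 12 * 11 // 2

    def test_matches_scalar_kabsch(self, rng):
        coords = rng.normal(size=(6, 8, 3)) * 2
        m = pairwise_matrix(list(range(6)), coords)
        for i in range(6):
            for j in range(i + 1, 6):
                assert m.values[i, j] == pytest.approx(
                    kabsch_rmsd(coords[i], coords[j]), abs=1e-9)

    def test_permutation_consistency(self, rng):
        coords = rng.normal(size=(7, 8, 3))
        m = pairwise_matrix(list(range(7)), coords)
        perm = rng.permutation(7)
        mp = pairwise_matrix(list(perm), coords[perm])
        assert np.allclose(mp.values, m.values[np.ix_(perm, perm)])

    def test_identical_windows_zero_matrix(self, rng):
        a = rng.normal(size=(8, 3))
        m = pairwise_matrix(list(range(3)), np.stack([a, a, a]))
        assert np.all(m.values < 1e-12)


class TestCompleteLinkage:
    def test_two_blocks(self, rng):
        base1 = rng.normal(size=(8, 3)) * 2
        base2 = base1 + np.array([20.0, 0, 0]) * rng.normal(size=(8, 3))
        coords = np.stack([base1 + rng.normal(0, 0.05, (8, 3))
                           for _ in range(4)]
                          + [base2 + rng.normal(0, 0.05, (8, 3))
                             for _ in range(4)])
        m = pairwise_matrix(list(range(8)), coords)
        res = complete_linkage_clusters(m, 3.0)
        assert res.n_clusters == 2 and not res.singlets
        groups = {frozenset(c) for c in res.clusters}
        assert groups == {frozenset(range(4)), frozenset(range(4, 8))}

    def test_all_separated_gives_singlets(self):
        values = np.full((5, 5), 10.0)
        np.fill_diagonal(values, 0.0)
        res = complete_linkage_clusters(RmsdMatrix(list("abcde"), values),
                                        3.0)
        assert res.n_clusters == 0 and len(res.singlets) == 5

    def test_diameter_guarantee_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 25))
            tri = rng.uniform(0, 6, size=(n, n))
            values = np.triu(tri, k=1)
            values = values + values.T
            m = RmsdMatrix(list(range(n)), values)
            res = complete_linkage_clusters(m, 3.0)
            for cluster in res.clusters:
                idx = [m.window_ids.index(w) for w in cluster]
                assert values[np.ix_(idx, idx)].max() <= 3.0

    def test_partition_property(self, rng):
        values = rng.uniform(0, 6, size=(15, 15))
        values = np.triu(values, 1)
        values += values.T
        m = RmsdMatrix(list(range(15)), values)
        res = complete_linkage_clusters(m, 3.0)
        members = sorted(w for c in res.clusters for w in c) \
            + sorted(res.singlets)
        assert sorted(members) == list(range(15))


class TestConsensusSs:
    def test_unanimous(self):
        ann = {i: "CCCHHHH" for i in range(3)}
        assert consensus_ss(list(range(3)), ann) == "CCCHHHH"

    def test_plurality(self):
        ann = {0: "HHHHHHH", 1: "HHHHHHH", 2: "EEEEEEE"}
        assert consensus_ss([0, 1, 2], ann) == "HHHHHHH"

    def test_tie_resolves_to_c(self):
        ann = {0: "HHHHHHH", 1: "EEEEEEE"}
        assert consensus_ss([0, 1], ann) == "CCCCCCC"

    def test_missing_member_abstains(self):
        ann = {0: "HHHHHHH"}
        assert consensus_ss([0, 1], ann) == "HHHHHHH"


class TestPlantedMotifRecovery:
    def test_k_templates_recovered(self):
        from sklearn.metrics import rand_score
        for k in (2, 4, 6):
            coords, truth = generate_window_set(k, 120, noise_sd=0.3,
                                                seed=k)
            m = pairwise_matrix(list(range(120)), coords)
            res = complete_linkage_clusters(m, 3.0)
            assert res.n_clusters == k
            labels = np.empty(120, dtype=int)
            for ci, cluster in enumerate(res.clusters):
                labels[list(cluster)] = ci
            for si, s in enumerate(res.singlets):
                labels[s] = 100 + si
            assert rand_score(truth, labels) >= 0.99


class TestBootstrapNull:
    def test_degenerate_pool_single_cluster(self, rng):
        base = template_window_atoms("HHHHHHH")
        coords = np.stack([base + rng.normal(0, 0.2, (8, 3))
                           for _ in range(20)])
        m = pairwise_matrix(list(range(20)), coords)
        null = bootstrap_null(m, n=10, reps=20, seed=5)
        assert np.all(null.counts == 1)

    def test_modal_count_matches_planted_k(self):
        k = 3
        coords, _ = generate_window_set(k, 60, noise_sd=0.3, seed=9)
        m = pairwise_matrix(list(range(60)), coords)
        null = bootstrap_null(m, n=60, reps=50, seed=1)
        values, counts = np.unique(null.counts, return_counts=True)
        assert values[np.argmax(counts)] == k

    def test_reproducible_for_fixed_seed(self, rng):
        coords = rng.normal(size=(15, 8, 3)) * 2
        m = pairwise_matrix(list(range(15)), coords)
        a = bootstrap_null(m, n=10, reps=15, seed=42)
        b = bootstrap_null(m, n=10, reps=15, seed=42)
        assert np.array_equal(a.counts, b.counts)

    def test_small_pool_warns(self, rng):
        coords = rng.normal(size=(3, 8, 3))
        m = pairwise_matrix(list(range(3)), coords)
        with pytest.warns(UserWarning, match="pool"):
            bootstrap_null(m, n=10, reps=5, seed=0)
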