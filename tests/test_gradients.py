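"""Gradient construction: correlation matrices, normalized-angle affinity,
diffusion embedding against an independent dense oracle, Procrustes
alignment, and global metrics."""

import numpy as np
import pytest

import fcgrad as fg
from fcgrad.gradients import ConnectivityMatrix

from conftest import dense_embedding_oracle, match_signs, random_affinity


class TestFcMatrix:
    def test_matches_textbook_pearson(self, rng):
        ts = rng.standard_normal((5, 10))
        fc = fg.fc_matrix(ts).values
        for i in range(5):
            for j in range(i + 1, 5):
                x, y = ts[i] - ts[i].mean(), ts[j] - ts[j].mean()
                r = (x @ y) / np.sqrt((x @ x) * (y @ y))
                assert fc[i, j] == pytest.approx(r, abs=1e-12)
        assert np.all(np.diag(fc) == 0)

    def test_identical_rows_give_r_one(self, rng):
        base = rng.standard_normal(20)
        ts = np.vstack([base, base, rng.standard_normal(20)])
        assert fg.fc_matrix(ts).values[0, 1] == pytest.approx(1.0)

    def test_orthogonal_sinusoids_uncorrelated(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        ts = np.vstack([np.sin(t), np.cos(t), np.sin(2 * t)])
        fc = fg.fc_matrix(ts).values
        assert abs(fc[0, 1]) < 1e-10

    def test_constant_row_rejected(self):
        ts = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="node"):
            fg.fc_matrix(ts)


class TestAffinity:
    def _fc_with_rows(self, rows: np.ndarray) -> ConnectivityMatrix:
        return ConnectivityMatrix(values=rows)

    def test_identical_rows_angle_one(self):
        # nodes 0 and 1 have identical connection profiles (and r01 = 0,
        # so the rows are equal element-wise after the diagonal is dropped)
        v = np.array(
            [
                [0.0, 0.0, 0.9, 0.8, 0.7],
                [0.0, 0.0, 0.9, 0.8, 0.7],
                [0.9, 0.9, 0.0, 0.5, 0.4],
                [0.8, 0.8, 0.5, 0.0, 0.3],
                [0.7, 0.7, 0.4, 0.3, 0.0],
            ]
        )
        aff = fg.affinity(self._fc_with_rows(v), density=0.99)
        assert aff.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_rows_angle_half(self):
        v = np.zeros((6, 6))
        v[0, 2] = v[2, 0] = 0.9
        v[1, 3] = v[3, 1] = 0.9
        v[2, 3] = v[3, 2] = 0.1
        v[4, 5] = v[5, 4] = 0.8
        v[0, 4] = v[4, 0] = 0.2
        v[1, 5] = v[5, 1] = 0.2
        aff = fg.affinity(self._fc_with_rows(v), density=0.99)
        # rows 0 and 1 have disjoint nonzero supports -> cosine 0 -> 0.5
        assert aff.values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_opposite_rows_angle_zero(self):
        v = np.array(
            [
                [0.0, 0.0, 0.9, -0.8],
                [0.0, 0.0, -0.9, 0.8],
                [0.9, -0.9, 0.0, 0.1],
                [-0.8, 0.8, 0.1, 0.0],
            ]
        )
        aff = fg.affinity(self._fc_with_rows(v), density=0.99)
        assert aff.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_density_bounds(self, rng):
        fc = fg.fc_matrix(rng.standard_normal((10, 30)))
        with pytest.raises(ValueError):
            fg.affinity(fc, density=0.0)
        with pytest.raises(ValueError):
            fg.affinity(fc, density=1.0)

    def test_row_sparsity_keeps_top_fraction(self, rng):
        fc = fg.fc_matrix(rng.standard_normal((40, 200)))
        from fcgrad.gradients import _sparsify_rows

        sparse = _sparsify_rows(fc.values, 0.10)
        k = int(np.ceil(0.10 * 39))
        for i in range(40):
            assert np.count_nonzero(sparse[i]) >= k
            kept = sparse[i][sparse[i] != 0]
            dropped = fc.values[i][(sparse[i] == 0) & (np.arange(40) != i)]
            assert kept.min() >= dropped.max()


class TestDiffusionEmbedding:
    def test_matches_dense_oracle(self, rng):
        for n in (15, 30, 50):
            a = random_affinity(rng, n)
            gs = fg.diffusion_embedding(a, k=3)
            oracle = dense_embedding_oracle(a, k=3)
            aligned = match_signs(gs.components, oracle)
            assert np.max(np.abs(gs.components - aligned)) < 1e-8

    def test_two_block_affinity_separated_by_gradient_one(self):
        a = np.full((20, 20), 0.1)
        a[:10, :10] = 0.9
        a[10:, 10:] = 0.9
        np.fill_diagonal(a, 0.0)
        g1 = fg.diffusion_embedding(a, k=2).components[:, 0]
        assert len(set(np.sign(g1[:10]))) == 1
        assert np.sign(g1[0]) == -np.sign(g1[10])

    def test_relabeling_equivariance(self, rng):
        a = random_affinity(rng, 25)
        perm = rng.permutation(25)
        g = fg.diffusion_embedding(a, k=3).components
        gp = fg.diffusion_embedding(a[np.ix_(perm, perm)], k=3).components
        assert np.allclose(match_signs(g[perm], gp), g[perm], atol=1e-8)

    def test_explained_ratios_sorted_and_bounded(self, rng):
        gs = fg.diffusion_embedding(random_affinity(rng, 30), k=5)
        er = gs.explained_ratio
        assert np.all(er >= 0)
        assert np.all(np.diff(er) <= 1e-12)
        assert er.sum() <= 1 + 1e-12

    def test_disconnected_affinity_rejected(self):
        a = np.zeros((10, 10))
        a[:5, :5] = 0.5
        a[5:, 5:] = 0.5
        np.fill_diagonal(a, 0.0)
        with pytest.raises(ValueError, match="density"):
            fg.diffusion_embedding(a, k=2)

    def test_k_must_be_less_than_n(self, rng):
        with pytest.raises(ValueError):
            fg.diffusion_embedding(random_affinity(rng, 10), k=10)


class TestProcrustes:
    def test_exact_recovery_of_orthogonal_copy(self, rng):
        g = rng.standard_normal((30, 4))
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        sets = [
            fg.GradientSet(components=m, eigenvalues=np.ones(4), explained_ratio=np.full(4, 0.1))
            for m in (g, g @ q)
        ]
        aligned, template = fg.procrustes_align(sets, n_iter=20)
        disparity = sum(np.sum((s.components - template) ** 2) for s in aligned)
        assert disparity < 1e-8

    def test_single_subject_unchanged_up_to_rotation(self, rng):
        g = rng.standard_normal((20, 3))
        s = fg.GradientSet(components=g, eigenvalues=np.ones(3), explained_ratio=np.full(3, 0.1))
        aligned, _ = fg.procrustes_align([s])
        # an orthogonal transform preserves the Gram matrix
        assert np.allclose(
            aligned[0].components @ aligned[0].components.T, g @ g.T, atol=1e-8
        )

    def test_disparity_never_increases(self, rng):
        from fcgrad.gradients import _disparity
        from scipy.linalg import orthogonal_procrustes

        mats = [rng.standard_normal((15, 3)) for _ in range(5)]
        template = np.mean(mats, axis=0)
        prev = _disparity(mats, template)
        for _ in range(6):
            for i, m in enumerate(mats):
                rot, _ = orthogonal_procrustes(m, template)
                mats[i] = m @ rot
            template = np.mean(mats, axis=0)
            cur = _disparity(mats, template)
            assert cur <= prev + 1e-10
            prev = cur

    def test_shape_mismatch_rejected(self, rng):
        a = fg.GradientSet(rng.standard_normal((10, 2)), np.ones(2), np.full(2, 0.1))
        b = fg.GradientSet(rng.standard_normal((12, 2)), np.ones(2), np.full(2, 0.1))
        with pytest.raises(ValueError):
            fg.procrustes_align([a, b])


class TestAxisRecovery:
    def test_group_mean_gradient_recovers_planted_axis(self):
        """The cohort's mean aligned gradient-1 map tracks the planted latent
        axis (|r| > 0.9 at 200 nodes, 500 timepoints, no compression)."""
        from fcgrad.pipeline import subject_gradients

        cohort = fg.gen_cohort(10, 10, n_nodes=200, n_timepoints=500,
                               compression=1.0, seed=31)
        _, g1, _ = subject_gradients(cohort)
        r = np.corrcoef(g1.mean(axis=0), cohort.truth.latent_axis)[0, 1]
        assert abs(r) > 0.9


class TestGlobalMetrics:
    def test_range_and_variance(self):
        comps = np.array([[-1.0], [0.0], [2.0]])
        gs = fg.GradientSet(comps, np.array([0.5]), np.array([0.3]))
        m = fg.global_metrics(gs)
        assert m.range == 3.0
        assert m.explained_ratio == pytest.approx(0.3)
        assert m.variance == pytest.approx(np.var([-1, 0, 2]))

    def test_constant_scores_degenerate(self):
        gs = fg.GradientSet(np.ones((5, 1)), np.array([0.5]), np.array([0.3]))
        m = fg.global_metrics(gs)
        assert m.range == 0.0 and m.variance == 0.0

    def test_sampling_variance_near_unit(self, rng):
        scores = rng.standard_normal((10000, 1))
        gs = fg.GradientSet(scores, np.array([0.5]), np.array([0.3]))
        assert fg.global_metrics(gs).variance == pytest.approx(1.0, rel=0.05)
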