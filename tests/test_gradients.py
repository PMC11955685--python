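import numpy as np
import pandas as pd
import pytest

from conngrad.gradients import (
    AffinityMatrix,
    build_template,
    compute_affinity,
    diffusion_map_embed,
    procrustes_align,
)
from conngrad.io import Connectome, RegionTable


def make_region_table(n, seed=0):
    rng = np.random.default_rng(seed)
    xyz = rng.standard_normal((n, 3))
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    half = n // 2
    df = pd.DataFrame(
        {
            "region_id": np.arange(n),
            "name": [f"r{i}" for i in range(n)],
            "hemisphere": ["L"] * half + ["R"] * (n - half),
            "network": ["Vis"] * n,
            "volume": np.ones(n),
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "is_cortical": True,
        }
    )
    return RegionTable(df)


def random_connectome(n, seed=0):
    rng = np.random.default_rng(seed)
    w = rng.random((n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    return Connectome(w, make_region_table(n, seed))


def random_affinity(n, rng):
    w = rng.random((n, n)) * 0.9 + 0.05
    w = (w + w.T) / 2
    np.fill_diagonal(w, 1.0)
    return AffinityMatrix(w, "cosine")


class TestComputeAffinity:
    def test_identical_profiles_similarity_one(self):
        # rows 0 and 1 agree on every column outside {0, 1}
        w = np.array(
            [
                [0, 2, 1, 1, 0.5],
                [2, 0, 1, 1, 0.5],
                [1, 1, 0, 1, 1.0],
                [1, 1, 1, 0, 1.0],
                [0.5, 0.5, 1, 1, 0],
            ],
            dtype=float,
        )
        aff = compute_affinity(Connectome(w, make_region_table(5)))
        assert aff.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_profiles_similarity_zero(self):
        w = np.array(
            [
                [0, 2, 1, 0, 0.0],
                [2, 0, 0, 1, 0.0],
                [1, 0, 0, 1, 1.0],
                [0, 1, 1, 0, 1.0],
                [0, 0, 1, 1, 0],
            ],
            dtype=float,
        )
        aff = compute_affinity(Connectome(w, make_region_table(5)))
        assert aff.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_cosine_half(self):
        # profiles over columns {2,3,4}: (1,1,0) vs (1,0,1) -> 1/2
        w = np.array(
            [
                [0, 2, 1, 1, 0.0],
                [2, 0, 1, 0, 1.0],
                [1, 1, 0, 1, 1.0],
                [1, 0, 1, 0, 1.0],
                [0, 1, 1, 1, 0],
            ],
            dtype=float,
        )
        aff = compute_affinity(Connectome(w, make_region_table(5)))
        assert aff.values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_cosine_matches_bruteforce_pair_loop(self, rng):
        conn = random_connectome(15, seed=4)
        aff = compute_affinity(conn).values
        w = conn.weights
        idx = np.arange(15)
        for i in range(15):
            for j in range(i + 1, 15):
                keep = (idx != i) & (idx != j)
                a, b = w[i, keep], w[j, keep]
                expect = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
                assert aff[i, j] == pytest.approx(max(expect, 0.0), abs=1e-10)

    @pytest.mark.parametrize("kernel", ["cosine", "spearman", "normalized_angle"])
    def test_kernel_output_invariants(self, kernel):
        aff = compute_affinity(random_connectome(12, seed=1), kernel=kernel)
        v = aff.values
        assert (v >= 0).all() and (v <= 1).all()
        np.testing.assert_allclose(v, v.T)
        np.testing.assert_allclose(np.diag(v), 1.0)

    def test_all_zero_row_names_region(self):
        w = np.ones((6, 6))
        np.fill_diagonal(w, 0)
        w[3, :] = w[:, 3] = 0
        with pytest.raises(ValueError, match=r"\[3\]"):
            compute_affinity(Connectome(w, make_region_table(6)))

    def test_weight_doubling_leaves_cosine_affinity_unchanged(self):
        conn = random_connectome(12, seed=9)
        doubled = Connectome(2 * conn.weights, conn.region_table)
        np.testing.assert_allclose(
            compute_affinity(conn).values, compute_affinity(doubled).values
        )


class TestDiffusionMapEmbed:
    def _oracle(self, w, alpha):
        """Independent dense route: eigendecompose the non-symmetric walk
        operator P = D'^-1 D^-a W D^-a directly."""
        d = w.sum(1)
        w1 = w / np.outer(d**alpha, d**alpha)
        p = w1 / w1.sum(1, keepdims=True)
        evals, evecs = np.linalg.eig(p)
        order = np.argsort(-evals.real)
        return evals.real[order], evecs.real[:, order]

    @pytest.mark.parametrize("alpha,t", [(0.5, 0), (0.2, 0), (0.8, 0), (0.5, 1)])
    def test_matches_dense_oracle(self, rng, alpha, t):
        for _ in range(10):
            aff = random_affinity(30, rng)
            gs = diffusion_map_embed(aff, n_components=5, alpha=alpha, t=t)
            evals, evecs = self._oracle(aff.values, alpha)
            np.testing.assert_allclose(gs.eigenvalues, evals[1:6], atol=1e-8)
            for c in range(5):
                got = gs.coordinates[:, c] / np.linalg.norm(gs.coordinates[:, c])
                ref = evecs[:, c + 1] / np.linalg.norm(evecs[:, c + 1])
                if got @ ref < 0:
                    ref = -ref
                np.testing.assert_allclose(got, ref, atol=1e-8)

    def test_two_block_structure_separated_by_g1(self):
        n = 10
        w = np.full((n, n), 1e-3)
        w[:5, :5] = 1.0
        w[5:, 5:] = 1.0
        np.fill_diagonal(w, 1.0)
        gs = diffusion_map_embed(AffinityMatrix(w, "cosine"), n_components=2)
        g1 = gs.coordinates[:, 0]
        assert len(set(np.sign(g1[:5]))) == 1
        assert np.sign(g1[0]) == -np.sign(g1[5])

    def test_region_permutation_equivariance(self, rng):
        aff = random_affinity(20, rng)
        perm = rng.permutation(20)
        permuted = AffinityMatrix(aff.values[np.ix_(perm, perm)], "cosine")
        a = diffusion_map_embed(aff, n_components=4)
        b = diffusion_map_embed(permuted, n_components=4)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)
        for c in range(4):
            ref = a.coordinates[perm, c]
            got = b.coordinates[:, c]
            if got @ ref < 0:
                got = -got
            np.testing.assert_allclose(got, ref, atol=1e-8)

    def test_uniform_affinity_rescale_invariance(self, rng):
        # the walk operator is invariant to uniform rescaling of the affinity
        aff = random_affinity(15, rng)
        gs1 = diffusion_map_embed(aff, n_components=3)
        gs2 = diffusion_map_embed(_raw(7.3 * aff.values), n_components=3)
        signs = np.sign(np.einsum("ij,ij->j", gs1.coordinates, gs2.coordinates))
        np.testing.assert_allclose(
            gs1.coordinates, gs2.coordinates * signs, atol=1e-8
        )

    def test_explained_variance_normalized(self, rng):
        gs = diffusion_map_embed(random_affinity(20, rng), n_components=6)
        assert gs.explained_variance.sum() == pytest.approx(1.0)
        assert (np.diff(gs.explained_variance) <= 1e-12).all()

    def test_disconnected_graph_lists_components(self):
        w = np.eye(6)
        w[:3, :3] = 1
        w[3:, 3:] = 1
        with pytest.raises(ValueError, match="components"):
            diffusion_map_embed(AffinityMatrix(w, "cosine"), n_components=2)

    def test_rejects_too_many_components(self, rng):
        with pytest.raises(ValueError):
            diffusion_map_embed(random_affinity(10, rng), n_components=10)


class _raw:
    """Duck-typed affinity wrapper bypassing the [0,1] entry validation."""

    def __init__(self, values):
        self.values = values


class TestProcrustes:
    def test_self_alignment_identity(self, rng):
        aff = random_affinity(20, rng)
        gs = diffusion_map_embed(aff, n_components=4)
        aligned, tr = procrustes_align(gs, gs)
        np.testing.assert_allclose(tr.rotation, np.eye(4), atol=1e-8)
        np.testing.assert_allclose(aligned.coordinates, gs.coordinates, atol=1e-8)

    def test_random_rotation_recovery(self, rng):
        from conngrad.gradients import GradientSet

        for _ in range(20):
            m = rng.standard_normal((30, 4))
            q, r = np.linalg.qr(rng.standard_normal((4, 4)))
            q *= np.sign(np.diag(r))
            template = GradientSet(m, np.zeros(4), np.zeros(4))
            source = GradientSet(m @ q.T, np.zeros(4), np.zeros(4))
            aligned, tr = procrustes_align(source, template)
            np.testing.assert_allclose(tr.rotation, q, atol=1e-8)
            assert np.linalg.norm(aligned.coordinates - m) < 1e-10

    def test_residual_never_worse_than_unaligned(self, rng):
        from conngrad.gradients import GradientSet

        for _ in range(20):
            g = rng.standard_normal((25, 3))
            m = rng.standard_normal((25, 3))
            aligned, _ = procrustes_align(
                GradientSet(g, np.zeros(3), np.zeros(3)),
                GradientSet(m, np.zeros(3), np.zeros(3)),
            )
            assert (
                np.linalg.norm(aligned.coordinates - m)
                <= np.linalg.norm(g - m) + 1e-12
            )

    def test_dimension_mismatch(self, rng):
        from conngrad.gradients import GradientSet

        a = GradientSet(rng.standard_normal((10, 3)), np.zeros(3), np.zeros(3))
        b = GradientSet(rng.standard_normal((12, 3)), np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError, match="mismatch"):
            procrustes_align(a, b)


class TestBuildTemplate:
    def test_identical_connectomes_match_individual(self):
        conn = random_connectome(20, seed=5)
        template = build_template([conn, conn, conn], n_components=4)
        gs = diffusion_map_embed(compute_affinity(conn), n_components=4)
        for c in range(4):
            a, b = template.coordinates[:, c], gs.coordinates[:, c]
            if a @ b < 0:
                b = -b
            np.testing.assert_allclose(a, b, atol=1e-8)

    def test_single_subject_template(self):
        conn = random_connectome(16, seed=6)
        t1 = build_template([conn], n_components=3)
        t2 = build_template([conn, conn], n_components=3)
        np.testing.assert_allclose(t1.coordinates, t2.coordinates, atol=1e-10)

    def test_sign_convention_against_centroid_axes(self):
        conns = [random_connectome(20, seed=s) for s in (1, 1, 1)]
        template = build_template(conns, n_components=3)
        axes = conns[0].region_table.centroids
        for c in range(3):
            g = template.coordinates[:, c]
            ref = axes[:, c]
            assert np.dot(g - g.mean(), ref - ref.mean()) >= 0

    def test_alignment_increases_between_subject_agreement(self, small_cohort):
        # aligned gradients of same-generator subjects correlate more than raw
        conns = small_cohort.connectomes[:6]
        template = build_template(conns, region_table=small_cohort.region_table)
        raw = [
            diffusion_map_embed(compute_affinity(c), n_components=10) for c in conns
        ]
        aligned = [procrustes_align(g, template)[0] for g in raw]

        def mean_abs_corr(sets):
            rs = []
            for i in range(len(sets)):
                for j in range(i + 1, len(sets)):
                    for c in range(3):
                        rs.append(
                            abs(np.corrcoef(sets[i].coordinates[:, c],
                                            sets[j].coordinates[:, c])[0, 1])
                        )
            return np.mean(rs)

        assert mean_abs_corr(aligned) >= mean_abs_corr(raw) - 1e-6
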