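"""Affinity construction, diffusion-map embedding, Procrustes, gradient features."""

import numpy as np
import pytest
import scipy.linalg

import connstates as cs
from conftest import random_connectivity


class TestRowwiseSparsify:
    def test_retained_count_per_row(self):
        cm = random_connectivity(400, seed=0, variant="GSR")
        S = cs.rowwise_sparsify(cm, 0.10)
        assert np.all((S != 0).sum(axis=1) == 40)  # round(0.10 * 399)

    def test_density_one_retains_all_off_diagonal(self):
        cm = random_connectivity(12, seed=1)
        S = cs.rowwise_sparsify(cm, 1.0)
        assert np.all((S != 0).sum(axis=1) == 11)
        assert np.all(np.diag(S) == 0)

    def test_weights_are_fisher_z_of_top_entries(self):
        cm = random_connectivity(20, seed=2)
        S = cs.rowwise_sparsify(cm, 0.2)
        k = round(0.2 * 19)
        for i in range(20):
            row = cm.values[i].copy()
            row[i] = -np.inf
            top = np.argsort(-row)[:k]
            assert np.allclose(np.sort(S[i, top]), np.sort(np.arctanh(row[top])), atol=1e-10)

    def test_tie_break_by_column_index(self):
        v = np.full((5, 5), 0.3)
        np.fill_diagonal(v, 1.0)
        S = cs.rowwise_sparsify(cs.ConnectivityMatrix(v, "GSR"), 0.25)  # k = 1
        # all candidates tie; the lowest admissible column index wins
        assert S[0, 1] != 0 and S[1, 0] != 0 and S[2, 0] != 0


class TestCosineAffinity:
    def test_identical_rows_affinity_one(self):
        S = np.tile(np.array([1.0, 2.0, 0.0, 1.0]), (3, 1))
        aff = cs.cosine_affinity(S)
        assert np.allclose(aff.values, 1.0)

    def test_orthogonal_rows_affinity_half(self):
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        aff = cs.cosine_affinity(S)
        assert aff.values[0, 1] == pytest.approx(0.5)

    def test_affinity_in_unit_interval(self, rng):
        S = np.abs(rng.standard_normal((15, 15)))
        aff = cs.cosine_affinity(S)
        assert aff.values.min() >= 0.0 and aff.values.max() <= 1.0

    def test_zero_row_names_parcel(self):
        S = np.ones((4, 4))
        S[2] = 0.0
        with pytest.raises(ValueError, match="parcel 2"):
            cs.cosine_affinity(S)


def two_block_affinity(n=20, high=0.9, low=0.1):
    half = n // 2
    v = np.full((n, n), low)
    v[:half, :half] = high
    v[half:, half:] = high
    np.fill_diagonal(v, 1.0)
    return cs.AffinityMatrix(values=v), half


class TestDiffusionEmbedding:
    def test_two_block_affinity_separated_by_first_gradient(self):
        aff, half = two_block_affinity()
        emb = cs.diffusion_embedding(aff)
        signs = np.sign(emb.coords[:, 0])
        assert len(set(signs[:half])) == 1
        assert len(set(signs[half:])) == 1
        assert signs[0] != signs[-1]

    def test_three_components_and_ordering(self):
        aff, _ = two_block_affinity()
        emb = cs.diffusion_embedding(aff)
        assert emb.coords.shape == (20, 3)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-12)

    def test_matches_dense_nonsymmetric_eigendecomposition(self):
        """Oracle: eigendecompose the row-stochastic operator M directly.

        Uses a generic affinity (random profiles) so the spectrum has no
        repeated eigenvalues and eigenvectors are unique up to sign.
        """
        g = np.random.default_rng(7)
        aff = cs.cosine_affinity(np.abs(g.standard_normal((20, 20))) + 0.1)
        W = aff.values
        d = W.sum(1)
        Wp = W / np.outer(d**0.5, d**0.5)
        M = Wp / Wp.sum(1)[:, None]
        evals, evecs = scipy.linalg.eig(M)
        order = np.argsort(-evals.real)
        evals = evals.real[order]
        evecs = evecs.real[:, order]
        emb = cs.diffusion_embedding(aff)
        assert np.allclose(emb.eigenvalues, evals[1:4], atol=1e-8)
        for k in range(3):
            v = evecs[:, k + 1]
            c = emb.coords[:, k]
            # same direction up to sign and scale
            cosang = abs(v @ c) / (np.linalg.norm(v) * np.linalg.norm(c))
            assert cosang == pytest.approx(1.0, abs=1e-8)

    def test_disconnected_affinity_is_an_error(self):
        v = np.zeros((8, 8))
        v[:4, :4] = 0.9
        v[4:, 4:] = 0.9
        np.fill_diagonal(v, 1.0)
        with pytest.raises(cs.DisconnectedAffinityError):
            cs.diffusion_embedding(cs.AffinityMatrix(values=v))

    def test_too_few_parcels_is_an_error(self):
        v = np.ones((3, 3))
        with pytest.raises(ValueError, match="at least"):
            cs.diffusion_embedding(cs.AffinityMatrix(values=v))


def random_embedding(rng, n=30):
    return cs.GradientEmbedding(coords=rng.standard_normal((n, 3)),
                                eigenvalues=np.array([0.5, 0.3, 0.2]))


class TestProcrustes:
    def test_identity_alignment(self, rng):
        e = random_embedding(rng)
        out = cs.procrustes_align(e, e)
        assert out.disparity == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(out.coords, e.coords, atol=1e-10)

    def test_sign_flip_recovered(self, rng):
        ref = random_embedding(rng)
        flipped = cs.GradientEmbedding(coords=ref.coords * np.array([-1, 1, -1]),
                                       eigenvalues=ref.eigenvalues)
        out = cs.procrustes_align(flipped, ref)
        assert np.allclose(out.coords, ref.coords, atol=1e-8)

    def test_random_rotation_round_trip(self, rng):
        ref = random_embedding(rng)
        R = scipy.linalg.qr(rng.standard_normal((3, 3)))[0]
        rotated = cs.GradientEmbedding(coords=ref.coords @ R, eigenvalues=ref.eigenvalues)
        out = cs.procrustes_align(rotated, ref)
        assert np.allclose(out.coords, ref.coords, atol=1e-8)

    def test_shape_mismatch_is_an_error(self, rng):
        e = random_embedding(rng, n=10)
        ref = random_embedding(rng, n=12)
        with pytest.raises(ValueError, match="mismatch"):
            cs.procrustes_align(e, ref)


class TestGradientFeatures:
    def test_emits_60_named_features(self, part21, rng):
        block = cs.gradient_feature_block(random_embedding(rng, 21), part21)
        assert len(block) == 60
        assert sum(":range:" in n for n in block.names) == 24
        assert sum(":disp:" in n for n in block.names) == 8
        assert sum(":ecc:" in n for n in block.names) == 7
        assert sum(":dist:" in n for n in block.names) == 21

    def test_degenerate_point_embedding_all_zero(self, part21):
        e = cs.GradientEmbedding(coords=np.ones((21, 3)),
                                 eigenvalues=np.array([0.5, 0.3, 0.2]))
        block = cs.gradient_feature_block(e, part21)
        assert np.allclose(block.values, 0.0)

    def test_between_network_distance_is_squared_distance(self, part21):
        coords = np.zeros((21, 3))
        coords[part21.indices("SMN"), 0] = 2.0  # VIS at origin, SMN at x=2
        e = cs.GradientEmbedding(coords=coords, eigenvalues=np.array([0.5, 0.3, 0.2]))
        s = cs.gradient_feature_block(e, part21).as_series()
        assert s["gradient:dist:VIS-SMN"] == pytest.approx(4.0)

    def test_law_of_total_variance_identity(self, part21, rng):
        """whole dispersion = sum over networks of (within + n_net * eccentricity)."""
        s = cs.gradient_feature_block(random_embedding(rng, 21), part21).as_series()
        total = sum(
            s[f"gradient:disp:{net}"] + 3 * s[f"gradient:ecc:{net}"]
            for net in part21.networks  # each network has 3 parcels
        )
        assert s["gradient:disp:whole"] == pytest.approx(total, abs=1e-8)

    def test_joint_rotation_invariance_after_alignment(self, part21, rng):
        """Rotating embedding and reference together leaves the distance-based
        features (dispersion, eccentricity, between-network distance)
        unchanged; per-axis ranges follow the reference frame by definition."""
        ref = random_embedding(rng, 21)
        e = random_embedding(rng, 21)
        R = scipy.linalg.qr(rng.standard_normal((3, 3)))[0]
        a = cs.gradient_feature_block(cs.procrustes_align(e, ref), part21).as_series()
        ref_rot = cs.GradientEmbedding(coords=ref.coords @ R, eigenvalues=ref.eigenvalues)
        e_rot = cs.GradientEmbedding(coords=e.coords @ R, eigenvalues=e.eigenvalues)
        b = cs.gradient_feature_block(cs.procrustes_align(e_rot, ref_rot), part21).as_series()
        invariant = [n for n in a.index if ":disp:" in n or ":ecc:" in n or ":dist:" in n]
        assert len(invariant) == 36
        assert np.allclose(a[invariant], b[invariant], atol=1e-8)

    def test_permuted_affinity_gives_permuted_features(self, part21, rng):
        """Embedding a permuted affinity equals the permuted embedding post-alignment."""
        cm = random_connectivity(21, seed=8, variant="GSR")
        emb = cs.embed_connectivity(cm, density=0.4)
        perm = rng.permutation(21)
        perm_cm = cs.ConnectivityMatrix(cm.values[np.ix_(perm, perm)], "GSR")
        perm_emb = cs.embed_connectivity(perm_cm, density=0.4)
        ref = cs.GradientEmbedding(coords=emb.coords[perm], eigenvalues=emb.eigenvalues)
        aligned = cs.procrustes_align(perm_emb, ref)
        assert np.allclose(aligned.coords, ref.coords, atol=1e-6)
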