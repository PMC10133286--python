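"""Autoencoder training, embedding, and reconstruction-score behaviour."""

import numpy as np
import pytest

import scregenai as s
from scregenai.autoencoder import FIDELITY_BENCHMARK
from scregenai.io_qc import ValidationError
from scregenai.simulate import simulate_low_rank

from conftest import make_norm


@pytest.fixture(scope="module")
def rank3_data():
    return simulate_low_rank(n_cells=500, n_genes=100, rank=3, noise_sd=0.05, seed=2)


@pytest.fixture(scope="module")
def trained(rank3_data):
    config = s.AutoencoderConfig(embedding_dim=10, seed=3, **FIDELITY_BENCHMARK)
    return s.train_autoencoder(rank3_data, config)


class TestTrainAutoencoder:
    def test_rank1_reconstruction_below_one_percent_of_variance(self):
        X = simulate_low_rank(n_cells=200, n_genes=50, rank=1, noise_sd=0.02, seed=4)
        config = s.AutoencoderConfig(embedding_dim=10, seed=5, **FIDELITY_BENCHMARK)
        model = s.train_autoencoder(X, config)
        score = s.reconstruction_similarity(X, s.embed(model, X).reconstruction)
        assert score.S < 0.01 * float(np.sum(X.var(axis=0)))

    def test_same_seed_reproduces_loss_trace(self, rank3_data):
        config = s.AutoencoderConfig(embedding_dim=10, epochs=30, seed=9)
        a = s.train_autoencoder(rank3_data, config)
        b = s.train_autoencoder(rank3_data, config)
        np.testing.assert_array_equal(a.loss_trace, b.loss_trace)

    def test_smoothed_loss_non_increasing(self, rank3_data):
        model = s.train_autoencoder(
            rank3_data, s.AutoencoderConfig(embedding_dim=10, seed=3)
        )
        smoothed = np.convolve(model.loss_trace, np.ones(10) / 10, mode="valid")
        running_min = np.minimum.accumulate(smoothed)
        assert (smoothed <= 1.05 * running_min).all()

    def test_l2_off_does_not_hurt_reconstruction(self, rank3_data):
        base = dict(embedding_dim=10, seed=3, sparsity_weight=0.0,
                    epochs=500, learning_rate=1e-2)
        with_l2 = s.train_autoencoder(
            rank3_data, s.AutoencoderConfig(l2_weight=1e-3, **base)
        )
        without = s.train_autoencoder(
            rank3_data, s.AutoencoderConfig(l2_weight=0.0, **base)
        )
        s_with = s.reconstruction_similarity(
            rank3_data, s.embed(with_l2, rank3_data).reconstruction
        ).S
        s_without = s.reconstruction_similarity(
            rank3_data, s.embed(without, rank3_data).reconstruction
        ).S
        assert s_without <= s_with

    def test_embedding_dim_must_be_smaller_than_genes(self):
        with pytest.raises(ValidationError, match="embedding_dim"):
            s.train_autoencoder(
                np.random.default_rng(0).normal(size=(20, 5)),
                s.AutoencoderConfig(embedding_dim=5, epochs=1),
            )

    def test_save_load_round_trip(self, trained, tmp_path, rank3_data):
        trained.save(tmp_path / "model.h5")
        back = s.AutoencoderModel.load(tmp_path / "model.h5")
        np.testing.assert_array_equal(back.encoder_weights, trained.encoder_weights)
        assert list(back.gene_ids) == list(trained.gene_ids)
        a = s.embed(trained, rank3_data)
        b = s.embed(back, rank3_data)
        np.testing.assert_allclose(a.coordinates, b.coordinates)


class TestEmbed:
    def test_identical_cells_identical_rows(self, trained):
        X = np.tile(np.linspace(0.0, 1.0, 100), (2, 1))
        result = s.embed(trained, X)
        np.testing.assert_array_equal(result.coordinates[0], result.coordinates[1])

    def test_coordinate_shape(self, trained, rank3_data):
        result = s.embed(trained, rank3_data)
        assert result.coordinates.shape == (500, 10)

    def test_training_reconstruction_matches_trace(self, trained, rank3_data):
        # final trace epoch of the benchmark recipe is pure reconstruction
        result = s.embed(trained, rank3_data)
        score = s.reconstruction_similarity(rank3_data, result.reconstruction)
        assert score.S == pytest.approx(trained.loss_trace[-1], rel=1e-9)

    def test_gene_list_mismatch_rejected(self, trained):
        norm = make_norm(np.zeros((3, 4)), genes=["x", "y", "z"])
        with pytest.raises(ValidationError, match="gene list mismatch"):
            s.embed(trained, norm)


class TestReconstructionSimilarity:
    def test_perfect_reconstruction_is_zero(self, rank3_data):
        assert s.reconstruction_similarity(rank3_data, rank3_data).S == 0.0

    def test_hand_arithmetic_single_cell(self):
        x = np.array([[1.0, 2.0, 3.0]])
        y = np.array([[1.0, 4.0, 3.0]])
        assert s.reconstruction_similarity(x, y).S == 4.0

    def test_gene_permutation_invariance(self, rank3_data, trained):
        recon = s.embed(trained, rank3_data).reconstruction
        perm = np.random.default_rng(0).permutation(100)
        a = s.reconstruction_similarity(rank3_data, recon).S
        b = s.reconstruction_similarity(rank3_data[:, perm], recon[:, perm]).S
        assert a == pytest.approx(b)

    def test_cell_order_invariance(self, rank3_data, trained):
        recon = s.embed(trained, rank3_data).reconstruction
        perm = np.random.default_rng(1).permutation(500)
        a = s.reconstruction_similarity(rank3_data, recon).S
        b = s.reconstruction_similarity(rank3_data[perm], recon[perm]).S
        assert a == pytest.approx(b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="shape"):
            s.reconstruction_similarity(np.zeros((2, 3)), np.zeros((2, 4)))


class TestPCAReconstruct:
    def test_rank1_single_component_exact(self):
        rng = np.random.default_rng(6)
        X = np.outer(rng.normal(size=30), rng.normal(size=8))
        recon = s.pca_reconstruct(X, 1)
        assert s.reconstruction_similarity(X, recon).S == pytest.approx(0.0, abs=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 5))
        recon = s.pca_reconstruct(X, 2)
        # oracle: explicit covariance eigenvectors
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / 6
        eigval, eigvec = np.linalg.eigh(cov)
        V = eigvec[:, np.argsort(eigval)[::-1][:2]]
        expected = X.mean(axis=0) + (Xc @ V) @ V.T
        np.testing.assert_allclose(recon, expected, atol=1e-8)

    def test_error_non_increasing_in_k(self, rank3_data):
        scores = [
            s.reconstruction_similarity(rank3_data, s.pca_reconstruct(rank3_data, k)).S
            for k in (1, 3, 5, 10, 20)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_infeasible_k_rejected(self):
        with pytest.raises(ValidationError, match="feasible"):
            s.pca_reconstruct(np.zeros((4, 3)), 5)


def test_autoencoder_not_worse_than_pca_at_intrinsic_rank(trained, rank3_data):
    """10-unit embedding of rank-3 data should match PCA-3's error budget."""
    s_ae = s.reconstruction_similarity(
        rank3_data, s.embed(trained, rank3_data).reconstruction
    ).S
    s_pca = s.reconstruction_similarity(
        rank3_data, s.pca_reconstruct(rank3_data, 3)
    ).S
    assert s_ae <= 1.1 * s_pca
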