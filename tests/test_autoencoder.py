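"""Masked autoencoder training: exact sparsity, learning, determinism."""

import numpy as np
import pytest

from scamine import (
    ConnectivityMask,
    TrainingConfig,
    encode,
    train_sca,
    train_vsca,
)
from scamine.autoencoder import TrainedModel

from conftest import make_counts


def small_problem(seed=0, n_genes=12, n_cells=40):
    rng = np.random.default_rng(seed)
    counts = make_counts(rng.poisson(3, (n_genes, n_cells)) + 0.0)
    mask = np.zeros((n_genes, 3), dtype=int)
    mask[0:5, 0] = 1
    mask[4:9, 1] = 1
    mask[8:12, 2] = 1
    cm = ConnectivityMask(list(counts.gene_ids), ["F0", "F1", "F2"], mask)
    return counts, cm


class TestTrainingConfig:
    def test_paper_optimizer_defaults(self):
        cfg = TrainingConfig()
        assert (cfg.learning_rate, cfg.beta_1, cfg.beta_2) == (0.01, 0.9, 0.999)
        assert cfg.epsilon == 1e-8 and cfg.decay == 0.0

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(epochs=0)


class TestMaskContract:
    def test_masked_weights_exactly_zero_after_one_step_and_after_training(self):
        counts, cm = small_problem()
        for epochs in (1, 25):
            model = train_sca(counts, cm, TrainingConfig(epochs=epochs, seed=1))
            off = cm.mask == 0
            assert np.all(model.encoder_weights[off] == 0.0)
            assert np.all(model.decoder_weights[off.T] == 0.0)

    def test_vsca_mask_holds_for_mean_and_logvar_heads(self):
        counts, cm = small_problem()
        model = train_vsca(counts, cm, TrainingConfig(epochs=5, seed=2))
        off = cm.mask == 0
        assert np.all(model.encoder_weights[off] == 0.0)
        assert np.all(model.logvar_weights[off] == 0.0)
        assert np.all(model.decoder_weights[off.T] == 0.0)


class TestLearning:
    def test_beats_per_gene_mean_predictor_on_planted_toy(self, planted_training):
        counts, mask, _ = planted_training
        model = train_sca(counts, mask, TrainingConfig(seed=3))
        baseline = float(counts.values.var(axis=1).mean())
        assert model.final_loss < baseline

    def test_loss_trend_non_increasing_averaged_over_seeds(self, planted_training):
        counts, mask, _ = planted_training
        traces = [
            train_sca(counts, mask, TrainingConfig(seed=s, epochs=40)).loss_history
            for s in range(5)
        ]
        mean = np.mean(traces, axis=0)
        checkpoints = mean[[0, 10, 20, 39]]
        assert np.all(np.diff(checkpoints) < 0)

    def test_bit_reproducible_given_seed(self, planted_training):
        counts, mask, _ = planted_training
        cfg = TrainingConfig(seed=11, epochs=10)
        m1 = train_sca(counts, mask, cfg)
        m2 = train_sca(counts, mask, cfg)
        assert np.array_equal(m1.encoder_weights, m2.encoder_weights)
        assert m1.final_loss == m2.final_loss

    def test_planted_feature_tracks_its_own_program(self, planted_training):
        counts, mask, toy = planted_training
        model = train_sca(counts, mask, TrainingConfig(seed=4))
        latent = encode(model, counts)
        X = counts.values.T
        for f, c in toy.feature_to_cluster.items():
            j = latent.feature_ids.index(f)
            own_genes = [counts.gene_ids.index(g) for g in sorted(toy.knowledge.edges[f])]
            other = [i for i in range(len(counts.gene_ids)) if i not in own_genes]
            own_mean = X[:, own_genes].mean(axis=1)
            other_mean = X[:, other].mean(axis=1)
            r_own = abs(np.corrcoef(latent.values[:, j], own_mean)[0, 1])
            r_other = abs(np.corrcoef(latent.values[:, j], other_mean)[0, 1])
            # independent linear check: own-program mean must explain more
            # latent variance than the rest of the transcriptome
            assert r_own > r_other

    def test_gene_mismatch_rejected(self, planted_training):
        counts, mask, _ = planted_training
        bad = make_counts(np.ones((3, 4)))
        with pytest.raises(ValueError):
            train_sca(bad, mask, TrainingConfig(epochs=1))


class TestVariational:
    def test_negative_kl_weight_rejected(self, planted_training):
        counts, mask, _ = planted_training
        with pytest.raises(ValueError):
            train_vsca(counts, mask, TrainingConfig(epochs=1), kl_weight=-1.0)

    def test_kl_finite_and_reconstruction_improves(self, planted_training):
        counts, mask, _ = planted_training
        kl_ends = []
        for s in range(3):
            model = train_vsca(counts, mask, TrainingConfig(seed=s, epochs=30))
            assert np.all(np.isfinite(model.kl_history))
            kl_ends.append(model.kl_history[-1])
            assert model.loss_history[-1] < model.loss_history[0]
        assert np.all(np.isfinite(kl_ends))

    def test_zero_kl_weight_removes_the_penalty_term(self, planted_training):
        counts, mask, _ = planted_training
        model = train_vsca(counts, mask, TrainingConfig(seed=5, epochs=5), kl_weight=0.0)
        X = counts.values.T
        mu = X @ model.encoder_weights + model.encoder_bias
        mse = float(np.mean((mu @ model.decoder_weights + model.decoder_bias - X) ** 2))
        assert model.final_loss == pytest.approx(mse)


class TestEncode:
    def test_reproduces_last_training_latent(self, planted_training):
        counts, mask, _ = planted_training
        for train in (train_sca, train_vsca):
            model = train(counts, mask, TrainingConfig(seed=6, epochs=5))
            latent = encode(model, counts)
            np.testing.assert_allclose(latent.values, model.final_latent, atol=1e-6)

    def test_zero_input_zero_bias_gives_zero_latent(self):
        counts, cm = small_problem()
        model = train_sca(counts, cm, TrainingConfig(epochs=1, seed=7))
        model.encoder_bias[:] = 0.0
        zeros = make_counts(np.zeros((counts.n_genes, 3)))
        zeros.gene_ids = list(counts.gene_ids)
        latent = encode(model, zeros)
        assert np.all(latent.values == 0.0)

    def test_cell_permutation_equivariance(self, planted_training):
        counts, mask, _ = planted_training
        model = train_sca(counts, mask, TrainingConfig(seed=8, epochs=3))
        perm = np.random.default_rng(0).permutation(counts.n_cells)
        direct = encode(model, counts).values[perm]
        permuted = encode(model, counts.subset_cells(perm)).values
        np.testing.assert_allclose(direct, permuted, atol=1e-12)

    def test_missing_genes_reported(self, planted_training):
        counts, mask, _ = planted_training
        truncated = counts.subset_genes(np.arange(counts.n_genes - 2))
        model = train_sca(counts, mask, TrainingConfig(seed=9, epochs=1))
        with pytest.raises(ValueError, match="missing"):
            encode(model, truncated)


class TestCheckpoint:
    def test_save_load_roundtrip(self, planted_training, tmp_path):
        counts, mask, _ = planted_training
        model = train_sca(counts, mask, TrainingConfig(seed=10, epochs=2))
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TrainedModel.load(path)
        np.testing.assert_array_equal(loaded.encoder_weights, model.encoder_weights)
        np.testing.assert_array_equal(loaded.decoder_weights, model.decoder_weights)
        assert loaded.variant == "sca" and loaded.seed == 10
        np.testing.assert_array_equal(
            encode(loaded, counts).values, encode(model, counts).values
        )
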