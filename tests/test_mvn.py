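"""Tokenization, masking, encoder/decoder shapes, freeze contract, and
small-scale training behaviour of the masked-autoencoder/ViT network."""
import numpy as np
import pytest

from mvnradar.config import MVNConfig
from mvnradar.mvn.model import (MaskedAutoencoder, build_mvn, patchify,
                                random_mask, unpatchify)
from mvnradar.mvn.training import finetune, predict, pretrain, tokenize_windows


@pytest.fixture(scope="module")
def tiny_cfg():
    return MVNConfig.desk_scale(seed=0, enc_layers=2, dec_layers=1, vit_layers=1,
                                enc_dim=16, dec_dim=16, vit_dim=16, heads=2,
                                ffn_dim=32)


class TestPatchify:
    def test_shapes(self):
        assert patchify(np.zeros((5, 128)), 8).shape == (16, 40)
        assert patchify(np.zeros((5, 256)), 8).shape == (32, 40)

    def test_round_trip_lossless(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(5, 128))
        assert np.array_equal(unpatchify(patchify(w, 8), 5, 8), w)

    def test_non_divisor_rejected(self):
        with pytest.raises(ValueError):
            patchify(np.zeros((5, 130)), 8)


class TestRandomMask:
    def test_forty_percent_of_100_tokens(self):
        visible, masked = random_mask(100, 0.40, np.random.default_rng(0))
        assert len(masked) == 40
        assert len(visible) == 60
        assert np.array_equal(np.sort(np.concatenate([visible, masked])),
                              np.arange(100))

    def test_same_seed_same_mask(self):
        a = random_mask(50, 0.4, np.random.default_rng(7))
        b = random_mask(50, 0.4, np.random.default_rng(7))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_uniform_masking_frequency(self):
        # each of 10 tokens masked with empirical frequency 0.4 +/- 3 SE
        rng = np.random.default_rng(3)
        counts = np.zeros(10)
        n_draws = 10_000
        for _ in range(n_draws):
            _, masked = random_mask(10, 0.4, rng)
            counts[masked] += 1
        freq = counts / n_draws
        se = np.sqrt(0.4 * 0.6 / n_draws)
        assert np.all(np.abs(freq - 0.4) < 3 * se)

    def test_degenerate_ratios_rejected(self):
        with pytest.raises(ValueError):
            random_mask(10, 0.01, np.random.default_rng(0))


class TestEncoderDecoder:
    def test_latent_count_is_visible_plus_class_token(self, tiny_cfg):
        mae = MaskedAutoencoder(tiny_cfg, 16, np.random.default_rng(0))
        tokens = np.random.default_rng(1).normal(size=(3, 16, tiny_cfg.patch_dim))
        vis, masked = mae.draw_masks(3, np.random.default_rng(2))
        latents = mae.encoder(tokens[np.arange(3)[:, None], vis], vis)
        assert latents.shape == (3, vis.shape[1] + 1, tiny_cfg.enc_dim)

    def test_reconstruction_covers_full_grid(self, tiny_cfg):
        mae = MaskedAutoencoder(tiny_cfg, 16, np.random.default_rng(0))
        tokens = np.random.default_rng(1).normal(size=(2, 16, tiny_cfg.patch_dim))
        vis, masked = mae.draw_masks(2, np.random.default_rng(2))
        recon = mae.forward(tokens, vis)
        assert recon.shape == (2, 16, tiny_cfg.patch_dim)

    def test_batch_equivariance(self, tiny_cfg):
        mae = MaskedAutoencoder(tiny_cfg, 16, np.random.default_rng(0))
        rng = np.random.default_rng(4)
        tokens = rng.normal(size=(4, 16, tiny_cfg.patch_dim))
        vis = np.tile(np.arange(10), (4, 1))
        out = mae.forward(tokens, vis).data
        perm = np.array([2, 0, 3, 1])
        out_perm = mae.forward(tokens[perm], vis).data
        assert np.allclose(out[perm], out_perm)

    def test_masked_and_unmasked_views_differ(self, tiny_cfg):
        mae = MaskedAutoencoder(tiny_cfg, 16, np.random.default_rng(0))
        rng = np.random.default_rng(5)
        tokens = rng.normal(size=(1, 16, tiny_cfg.patch_dim))
        vis, _ = mae.draw_masks(1, rng)
        full = np.arange(16)[None, :]
        lat_masked = mae.encoder(tokens[0:1, vis[0]], vis)
        lat_full = mae.encoder(tokens, full)
        assert lat_full.shape[1] == 17
        assert not np.allclose(lat_masked.data[:, 0], lat_full.data[:, 0])


class TestMVNModel:
    def test_predict_scalar_finite_on_zero_window(self, tiny_cfg):
        mae = MaskedAutoencoder(tiny_cfg, 16, np.random.default_rng(0))
        model = build_mvn(mae.encoder, tiny_cfg, 16)
        out = predict(model, np.zeros((5, 128)))
        assert out.shape == (1,) and np.isfinite(out[0])

    def test_predict_deterministic_and_batch_consistent(self, tiny_cfg):
        mae = MaskedAutoencoder(tiny_cfg, 16, np.random.default_rng(0))
        model = build_mvn(mae.encoder, tiny_cfg, 16)
        rng = np.random.default_rng(6)
        X = rng.normal(size=(3, 5, 128))
        batch = predict(model, X)
        assert np.array_equal(batch, predict(model, X))
        singles = np.concatenate([predict(model, X[i]) for i in range(3)])
        assert np.allclose(batch, singles)

    def test_encoder_frozen_during_finetune(self, tiny_cfg, toy_sinusoid_windows):
        X, y = toy_sinusoid_windows
        mae = MaskedAutoencoder(tiny_cfg, 16, np.random.default_rng(0))
        model = build_mvn(mae.encoder, tiny_cfg, 16)
        before = model.encoder.checksum()
        model, _ = finetune(model, X[:40], y[:40], tiny_cfg, epochs=3)
        assert model.encoder.checksum() == before

    def test_unfrozen_encoder_changes(self, tiny_cfg, toy_sinusoid_windows):
        X, y = toy_sinusoid_windows
        mae = MaskedAutoencoder(tiny_cfg, 16, np.random.default_rng(0))
        model = build_mvn(mae.encoder, tiny_cfg, 16, encoder_frozen=False)
        before = model.encoder.checksum()
        model, _ = finetune(model, X[:40], y[:40], tiny_cfg, epochs=2)
        assert model.encoder.checksum() != before


class TestTraining:
    def test_loss_history_length_and_seed_determinism(self, tiny_cfg, toy_sinusoid_windows):
        X, _ = toy_sinusoid_windows
        _, h1 = pretrain(X[:40], tiny_cfg, epochs=3)
        _, h2 = pretrain(X[:40], tiny_cfg, epochs=3)
        assert len(h1.train_loss) == 3 and len(h1.val_loss) == 3
        assert h1.train_loss == h2.train_loss  # bit-identical numpy path

    def test_pretraining_improves_masked_reconstruction(self, toy_sinusoid_windows):
        # on clean sinusoid windows the best checkpoint must beat the
        # untrained model by a wide margin (>= 10x lower masked MSE)
        X, _ = toy_sinusoid_windows
        cfg = MVNConfig.desk_scale(seed=0)
        mae, hist = pretrain(X, cfg, epochs=150)
        assert hist.best_val < hist.val_loss[0] / 10.0

    def test_finetune_reduces_training_mse(self, tiny_cfg, toy_sinusoid_windows):
        X, y = toy_sinusoid_windows
        mae = MaskedAutoencoder(tiny_cfg, 16, np.random.default_rng(0))
        model = build_mvn(mae.encoder, tiny_cfg, 16, encoder_frozen=False)
        model, hist = finetune(model, X, y, tiny_cfg, epochs=30)
        assert min(hist.train_loss) < hist.train_loss[0]
        assert hist.best_val <= hist.val_loss[0]

    def test_degenerate_labels_warn(self, tiny_cfg, toy_sinusoid_windows):
        X, _ = toy_sinusoid_windows
        mae = MaskedAutoencoder(tiny_cfg, 16, np.random.default_rng(0))
        model = build_mvn(mae.encoder, tiny_cfg, 16)
        with pytest.warns(UserWarning):
            finetune(model, X[:8], np.full(8, 72.0), tiny_cfg, epochs=1)

    def test_empty_dataset_rejected(self, tiny_cfg):
        with pytest.raises(ValueError):
            pretrain(np.zeros((0, 5, 128)), tiny_cfg)


def test_tokenize_windows_shape():
    X = np.random.default_rng(0).normal(size=(7, 5, 128))
    assert tokenize_windows(X, 8).shape == (7, 16, 40)
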