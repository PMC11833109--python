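"""Architecture contracts, the two-phase training schedule, and the
3D-only / fused model relationship."""

import numpy as np
import pytest

from cytofuse.config import LossWeights, TrainingConfig
from cytofuse.errors import ConfigurationError, InputError
from cytofuse import cae_models as cm
from cytofuse.cae_models import (CAE3DClassifier, CellImageDataset,
                                 ReconstructionBatch,
                                 build_3d_cae, build_fused_cae,
                                 encode_latent, mse_loss, normalize_images,
                                 predict, train)

SHAPE_3D = (10, 16, 16)
SHAPE_2D = (16, 16)


def small_config(**kw):
    defaults = dict(total_epochs=3, recon_only_epochs=1, batch_size=4,
                    latent_dim=8, conv_channels=(4, 8), seed=5)
    defaults.update(kw)
    return TrainingConfig(**defaults)


class TestArchitecture:
    def test_fused_forward_contract(self, stress_dataset):
        model = build_fused_cae(small_config(), SHAPE_3D, SHAPE_2D)
        out = model.forward(stress_dataset.x_3d[:4], stress_dataset.x_2d[:4])
        assert out["recon"]["3d"].shape == stress_dataset.x_3d[:4].shape
        assert out["recon"]["2d"].shape == stress_dataset.x_2d[:4].shape
        assert out["probs"].shape == (4, 2)
        np.testing.assert_allclose(out["probs"].sum(axis=1), 1.0, atol=1e-6)
        assert np.all(out["probs"] > 0)

    def test_fused_head_consumes_concatenated_latents(self, stress_dataset):
        cfg = small_config(latent_dim=8)
        model = build_fused_cae(cfg, SHAPE_3D, SHAPE_2D)
        assert model.head.W.value.shape[0] == 2 * cfg.latent_dim
        z = encode_latent(model, stress_dataset.x_3d[:3],
                          stress_dataset.x_2d[:3])
        assert z.shape == (3, 2 * cfg.latent_dim)

    def test_3d_only_head_consumes_3d_latent_only(self, stress_dataset):
        cfg = small_config(loss_weights=LossWeights(w1=0.0))
        model = build_3d_cae(cfg, SHAPE_3D)
        assert model.head.W.value.shape[0] == cfg.latent_dim
        z = encode_latent(model, stress_dataset.x_3d[:3])
        assert z.shape == (3, cfg.latent_dim)

    def test_3d_only_rejects_positive_w1(self):
        with pytest.raises(ConfigurationError, match="w1"):
            CAE3DClassifier(small_config(loss_weights=LossWeights(w1=0.5)),
                            SHAPE_3D)

    def test_deterministic_initialization(self, stress_dataset):
        a = build_fused_cae(small_config(), SHAPE_3D, SHAPE_2D)
        b = build_fused_cae(small_config(), SHAPE_3D, SHAPE_2D)
        pa = predict(a, stress_dataset.x_3d[:2], stress_dataset.x_2d[:2])
        pb = predict(b, stress_dataset.x_3d[:2], stress_dataset.x_2d[:2])
        np.testing.assert_array_equal(pa, pb)

    def test_predict_is_pure(self, stress_dataset):
        model = build_fused_cae(small_config(), SHAPE_3D, SHAPE_2D)
        p1 = predict(model, stress_dataset.x_3d, stress_dataset.x_2d)
        p2 = predict(model, stress_dataset.x_3d, stress_dataset.x_2d)
        np.testing.assert_array_equal(p1, p2)
        assert p1.shape == (len(stress_dataset), 2)

    def test_indivisible_spatial_dims_rejected(self):
        with pytest.raises(ConfigurationError):
            build_fused_cae(small_config(conv_channels=(4, 8, 16)),
                            (10, 10, 10), (10, 10))

    def test_reduction_to_3d_model(self, stress_dataset):
        """With w1 = 0 the fused model's reconstruction loss equals the
        3D-only model's bit-for-bit on identical 3D inputs (the 3D
        branch is the shared sub-network)."""
        cfg = small_config(loss_weights=LossWeights(w1=0.0))
        fused = build_fused_cae(cfg, SHAPE_3D, SHAPE_2D)
        only3d = build_3d_cae(cfg, SHAPE_3D)
        x3 = stress_dataset.x_3d[:4]
        x2 = stress_dataset.x_2d[:4]
        out_f = fused.forward(x3, x2)
        out_3 = only3d.forward(x3)
        l_f = mse_loss(ReconstructionBatch(x3, out_f["recon"]["3d"],
                                           x2, out_f["recon"]["2d"]), 0.0)
        l_3 = mse_loss(ReconstructionBatch(x3, out_3["recon"]["3d"]), 0.0)
        assert l_f == l_3


class TestTraining:
    def test_history_bookkeeping(self, stress_dataset):
        cfg = small_config(total_epochs=4, recon_only_epochs=2)
        model = build_fused_cae(cfg, SHAPE_3D, SHAPE_2D)
        _, history = train(model, stress_dataset, cfg)
        assert len(history) == 4
        assert [h["phase"] for h in history] == ["recon", "recon",
                                                 "joint", "joint"]
        for h in history:
            assert np.isfinite(h["l_mse"]) and np.isfinite(h["l_ce"])
            assert h["l_mse"] >= 0 and h["l_ce"] >= 0

    def test_recon_only_schedule_freezes_classifier_head(self, stress_dataset):
        """A run that never leaves the reconstruction phase leaves the
        classification head exactly at its initialization."""
        cfg = small_config(total_epochs=2, recon_only_epochs=2)
        model = build_fused_cae(cfg, SHAPE_3D, SHAPE_2D)
        w0 = model.head.W.value.copy()
        b0 = model.head.b.value.copy()
        _, history = train(model, stress_dataset, cfg)
        np.testing.assert_array_equal(model.head.W.value, w0)
        np.testing.assert_array_equal(model.head.b.value, b0)
        assert all(h["phase"] == "recon" for h in history)

    def test_joint_phase_moves_classifier_head(self, stress_dataset):
        cfg = small_config(total_epochs=2, recon_only_epochs=0)
        model = build_fused_cae(cfg, SHAPE_3D, SHAPE_2D)
        w0 = model.head.W.value.copy()
        train(model, stress_dataset, cfg)
        assert not np.array_equal(model.head.W.value, w0)

    def test_unlabeled_dataset_rejected(self, stress_dataset):
        cfg = small_config()
        data = CellImageDataset(stress_dataset.x_3d, stress_dataset.x_2d,
                                None)
        with pytest.raises(InputError):
            train(build_fused_cae(cfg, SHAPE_3D, SHAPE_2D), data, cfg)

    def test_training_reproducible_given_seed(self, stress_dataset):
        cfg = small_config(total_epochs=2)
        h1 = train(build_fused_cae(cfg, SHAPE_3D, SHAPE_2D),
                   stress_dataset, cfg)[1]
        h2 = train(build_fused_cae(cfg, SHAPE_3D, SHAPE_2D),
                   stress_dataset, cfg)[1]
        assert h1 == h2

    def test_loss_decreases_on_separable_data(self):
        """200-cell high-effect dataset, reduced protocol: the optimized
        epoch-mean loss strictly decreases start to finish."""
        from cytofuse.config import SimConfig
        from cytofuse import synthetic_data
        sim = SimConfig(n_cells=200, image_height=16, image_width=16,
                        trans_height=16, trans_width=16,
                        scenario="gfp_production", effect_size=2.0, seed=31)
        records = synthetic_data.simulate_population(sim)
        data = CellImageDataset.from_records(records, use_2d=False)
        cfg = TrainingConfig(total_epochs=30, recon_only_epochs=4,
                             batch_size=4, latent_dim=16,
                             conv_channels=(4, 8, 16), seed=9,
                             loss_weights=LossWeights(w1=0.0))
        model = build_3d_cae(cfg, data.x_3d.shape[2:])
        _, history = train(model, data, cfg)
        assert history[-1]["l_total"] < history[0]["l_total"]
        # and the reconstruction itself improved over the run
        assert history[-1]["l_mse"] < history[0]["l_mse"]


class TestSerialization:
    def test_save_load_round_trip(self, stress_dataset, tmp_path):
        cfg = small_config(total_epochs=1, recon_only_epochs=0)
        model = build_fused_cae(cfg, SHAPE_3D, SHAPE_2D)
        train(model, stress_dataset, cfg)
        cm.save_model(model, tmp_path / "ckpt")
        loaded = cm.load_model(tmp_path / "ckpt")
        p1 = predict(model, stress_dataset.x_3d[:4], stress_dataset.x_2d[:4])
        p2 = predict(loaded, stress_dataset.x_3d[:4], stress_dataset.x_2d[:4])
        np.testing.assert_array_equal(p1, p2)


class TestNormalization:
    def test_per_image_min_max(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 3, size=(4, 3, 3))
        z = normalize_images(x)
        for img in z:
            assert img.min() == pytest.approx(0.0)
            assert img.max() == pytest.approx(1.0)

    def test_constant_image_is_safe(self):
        z = normalize_images(np.full((2, 3, 3), 7.0))
        assert np.all(np.isfinite(z))
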