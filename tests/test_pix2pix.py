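"""Conditional-GAN tracer: contracts, determinism, serialization and a
small learning check.  Training-quality statistics live in the acceptance
suite; here the configurations are tiny (64-px patches, few epochs)."""

import numpy as np
import pandas as pd
import pytest

from pnnmesh import (
    DiscriminatorSpec,
    GeneratorSpec,
    LatticeParams,
    RenderParams,
    TrainConfig,
    build_models,
    load_model,
    make_patch_dataset,
    predict_mask,
    save_model,
    split_dataset,
    train,
)
from pnnmesh.pix2pix import Pix2PixTracer

TINY_GEN = GeneratorSpec(depth=4, base_channels=8, channel_cap=16)
TINY_DISC = DiscriminatorSpec(n_layers=2, base_channels=8)


@pytest.fixture(scope="module")
def tiny_train_data():
    lat = LatticeParams(n_meshes=30, mean_mesh_diameter=24, domain_size=(256, 256))
    rend = RenderParams.for_regime("high_contrast").noiseless()
    ds = make_patch_dataset(1, lat, rend, patch_size=64, seed=1)
    return split_dataset(ds, 0.8, seed=1)


@pytest.fixture(scope="module")
def tiny_trained(tiny_train_data):
    train_set, test_set = tiny_train_data
    model = build_models(TINY_GEN, TINY_DISC, patch_size=64, seed=0)
    cfg = TrainConfig(epochs=3, batch_size=4, patch_size=64, seed=0)
    model, history, _ = train(model, train_set, cfg, eval_set=test_set)
    return model, history, test_set


class TestBuildModels:
    def test_bottleneck_collapse_rejected(self):
        with pytest.raises(ValueError):
            build_models(GeneratorSpec(depth=6), patch_size=64)

    def test_output_shape_matches_input(self):
        model = build_models(GeneratorSpec(depth=5, base_channels=8, channel_cap=16),
                             TINY_DISC, patch_size=128, seed=0)
        x = np.zeros((1, 1, 128, 128), np.float32)
        assert model.generator.forward(x).shape == x.shape

    def test_seeded_init_reproducible(self):
        a = build_models(TINY_GEN, TINY_DISC, patch_size=64, seed=7)
        b = build_models(TINY_GEN, TINY_DISC, patch_size=64, seed=7)
        assert a.checksum() == b.checksum()

    def test_receptive_field_must_fit_patch(self):
        with pytest.raises(ValueError):
            build_models(TINY_GEN, DiscriminatorSpec(n_layers=5), patch_size=64)


class TestTraining:
    def test_loss_history_one_row_per_epoch(self, tiny_trained):
        _, history, _ = tiny_trained
        assert len(history) == 3
        for col in ("gen_adv_loss", "gen_l1_loss", "disc_loss", "test_l1"):
            assert np.isfinite(history[col]).all()

    def test_l1_weight_reduces_reconstruction_error(self, tiny_train_data):
        """Paired seeded runs: lambda_l1 = 100 ends with a lower mean L1
        distance to the targets than lambda_l1 = 0."""
        train_set, test_set = tiny_train_data
        finals = {}
        for lam in (0.0, 100.0):
            model = build_models(TINY_GEN, TINY_DISC, patch_size=64, seed=0)
            cfg = TrainConfig(epochs=3, batch_size=4, patch_size=64, seed=0, lambda_l1=lam)
            _, history, _ = train(model, train_set, cfg, eval_set=test_set)
            finals[lam] = history["test_l1"].iloc[-1]
        assert finals[100.0] < finals[0.0]

    def test_snapshot_epochs_recorded(self, tiny_train_data):
        train_set, _ = tiny_train_data
        model = build_models(TINY_GEN, TINY_DISC, patch_size=64, seed=0)
        cfg = TrainConfig(epochs=2, batch_size=4, patch_size=64, seed=0,
                          snapshot_epochs=(1, 2))
        _, _, snaps = train(model, train_set, cfg)
        assert sorted(snaps) == [1, 2]
        assert all(v.ndim == 4 for v in snaps.values())

    def test_empty_train_set_rejected(self, tiny_train_data):
        _, test_set = tiny_train_data
        empty = test_set.subset([])
        model = build_models(TINY_GEN, TINY_DISC, patch_size=64, seed=0)
        with pytest.raises(ValueError):
            train(model, empty, TrainConfig(epochs=1, patch_size=64))

    def test_training_is_seeded(self, tiny_train_data):
        train_set, _ = tiny_train_data
        sums = []
        for _ in range(2):
            model = build_models(TINY_GEN, TINY_DISC, patch_size=64, seed=3)
            _, history, _ = train(
                model, train_set, TrainConfig(epochs=1, batch_size=4, patch_size=64, seed=3)
            )
            sums.append((model.checksum(), history["gen_l1_loss"].iloc[-1]))
        assert sums[0] == sums[1]


class TestPrediction:
    def test_output_range_and_shape(self, tiny_trained):
        model, _, test_set = tiny_trained
        out = predict_mask(model, test_set.samples[0].image)
        assert out.shape == (64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_deterministic(self, tiny_trained):
        model, _, test_set = tiny_trained
        a = predict_mask(model, test_set.samples[0].image)
        b = predict_mask(model, test_set.samples[0].image)
        assert np.array_equal(a, b)

    def test_shape_mismatch_rejected(self, tiny_trained):
        model, _, _ = tiny_trained
        with pytest.raises(ValueError):
            predict_mask(model, np.zeros((32, 32), np.float32))

    def test_mask_brighter_on_contour_than_background(self, tiny_trained):
        """Even a briefly trained model responds more on the true contour
        pixels of a held-out clean patch than on the background."""
        model, _, test_set = tiny_trained
        s = test_set.samples[0]
        out = predict_mask(model, s.image)
        on = out[s.target > 0].mean()
        off = out[s.target == 0].mean()
        assert on > off

    def test_serialization_round_trip_bit_identical(self, tiny_trained, tmp_path):
        model, _, test_set = tiny_trained
        path = tmp_path / "ckpt.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.checksum() == model.checksum()
        a = predict_mask(model, test_set.samples[1].image)
        b = predict_mask(loaded, test_set.samples[1].image)
        assert np.array_equal(a, b)
        assert loaded.epoch == model.epoch


class TestModelResultsFrontend:
    def test_fit_returns_results_with_summary(self, tiny_train_data):
        train_set, test_set = tiny_train_data
        tracer = Pix2PixTracer(train_set, eval_set=test_set,
                               gen_spec=TINY_GEN, disc_spec=TINY_DISC)
        res = tracer.fit(TrainConfig(epochs=1, batch_size=4, patch_size=64, seed=0))
        assert isinstance(res.loss_history, pd.DataFrame)
        text = res.summary()
        assert "PatchGAN" in text and "U-Net" in text
        out = res.predict_mask(test_set.samples[0].image)
        assert out.shape == (64, 64)
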