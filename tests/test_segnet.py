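"""Segmentation network: contracts, determinism, round trips, learnability."""

import numpy as np
import pytest

from fruitseg import (
    NetworkConfig,
    TrainHyperparams,
    build_model,
    generate_dataset,
    load_model,
    predict_mask,
    save_model,
    scene_specs,
    train,
)
from fruitseg.metrics import evaluate_predictions
from fruitseg.nn import Conv2d, softmax_cross_entropy


def small_config(seed=0, size=(64, 64)):
    return NetworkConfig(backbone="tiny", input_size=size, seed=seed)


class TestBuildModel:
    def test_output_shape_contract(self):
        model = build_model(small_config())
        x = np.zeros((1, 3, 64, 64), dtype=np.float32)
        out = model.net.forward(x)
        assert out.shape == (1, 2, 64, 64)

    def test_num_classes_fixed_at_two(self):
        with pytest.raises(ValueError):
            NetworkConfig(num_classes=3)

    def test_aspp_rates_must_increase(self):
        with pytest.raises(ValueError):
            NetworkConfig(aspp_rates=(2, 2, 4))
        with pytest.raises(ValueError):
            NetworkConfig(aspp_rates=())

    def test_identical_seeds_give_identical_initial_parameters(self):
        a = build_model(small_config(seed=3))
        b = build_model(small_config(seed=3))
        for (ka, va), (kb, vb) in zip(
            a.net.state_dict().items(), b.net.state_dict().items()
        ):
            assert ka == kb
            assert np.array_equal(va, vb)

    def test_missing_pretrained_weights_raise(self, tmp_path):
        cfg = NetworkConfig(pretrained_weights=str(tmp_path / "absent.npz"))
        with pytest.raises(FileNotFoundError):
            build_model(cfg)


class TestPredictMask:
    def test_untrained_model_rejected(self):
        model = build_model(small_config())
        with pytest.raises(ValueError):
            predict_mask(model, np.zeros((64, 64, 3), dtype=np.uint8))

    def test_binary_output_with_input_shape(self, set1_scene):
        model = build_model(small_config())
        model.trained = True  # exercise the inference path directly
        m = predict_mask(model, set1_scene.image)
        assert m.shape == set1_scene.image.shape[:2]
        assert set(np.unique(m)) <= {0, 1}

    def test_tied_scores_break_toward_background(self):
        model = build_model(small_config())
        # zero every parameter: both class channels output identically
        for layer in model.net.conv_layers():
            layer.W[:] = 0.0
            layer.b[:] = 0.0
        model.trained = True
        m = predict_mask(model, np.full((64, 64, 3), 90, dtype=np.uint8))
        assert m.sum() == 0


class TestGradients:
    def test_conv_backward_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        conv = Conv2d(2, 3, kernel=3, stride=2, rng=rng)
        x = rng.normal(size=(1, 2, 8, 8)).astype(np.float32)
        y = conv.forward(x)
        g = rng.normal(size=y.shape).astype(np.float32)
        conv.backward(g)
        eps = 1e-3
        idx = (1, 4)  # one weight entry (out channel, flattened tap)
        w0 = conv.W[idx]
        conv.W[idx] = w0 + eps
        lp = float((conv.forward(x) * g).sum())
        conv.W[idx] = w0 - eps
        lm = float((conv.forward(x) * g).sum())
        conv.W[idx] = w0
        assert conv.dW[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-2)

    def test_cross_entropy_gradient_sums_to_zero_per_pixel(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(2, 2, 4, 4)).astype(np.float32)
        target = rng.integers(0, 2, size=(2, 4, 4))
        loss, grad = softmax_cross_entropy(logits, target)
        assert loss > 0
        assert np.allclose(grad.sum(axis=1), 0.0, atol=1e-6)


class TestTraining:
    @pytest.fixture(scope="class")
    @classmethod
    def trained(cls):
        ds = generate_dataset(scene_specs("set1", 40, 3))
        model = build_model(small_config())
        hp = TrainHyperparams(epochs=10, batch_size=8, seed=0)
        return train(model, ds, hp, stage_tag="manual"), ds

    def test_learns_set1_benchmark(self, trained):
        model, _ = trained
        test = generate_dataset(scene_specs("set1", 10, 4))
        preds = [predict_mask(model, s.image) for s in test]
        rep = evaluate_predictions(preds, [s.mask for s in test])
        assert rep.averages["f1"] >= 0.9
        # an untrained net does not reach this (sanity separation)
        fresh = build_model(small_config(seed=9))
        fresh.trained = True
        base = evaluate_predictions(
            [predict_mask(fresh, s.image) for s in test], [s.mask for s in test]
        )
        assert base.averages["f1"] < 0.9

    def test_memorizes_training_image(self, trained):
        model, ds = trained
        pred = predict_mask(model, ds[0].image)
        rep = evaluate_predictions([pred], [ds[0].mask])
        assert rep.averages["f1"] >= 0.9

    def test_loss_logged_and_finite(self, trained):
        model, _ = trained
        assert len(model.history) == 10
        assert all(np.isfinite(h["loss"]) for h in model.history)

    def test_training_is_deterministic(self):
        ds = generate_dataset(scene_specs("set1", 6, 5, (32, 32)))
        hp = TrainHyperparams(epochs=2, batch_size=4, seed=7)
        runs = []
        for _ in range(2):
            m = build_model(small_config(seed=2, size=(32, 32)))
            train(m, ds, hp, stage_tag="manual")
            runs.append(m.history[-1]["loss"])
        assert runs[0] == runs[1]

    def test_zero_mask_training_predicts_almost_no_fruit(self):
        negs = generate_dataset(scene_specs("negative", 12, 6, (32, 32)))
        model = build_model(small_config(size=(32, 32)))
        train(model, negs, TrainHyperparams(epochs=4, batch_size=4, seed=0),
              stage_tag="tna")
        held_out = generate_dataset(scene_specs("negative", 6, 60, (32, 32)))
        frac = np.mean(
            [predict_mask(model, s.image).mean() for s in held_out]
        )
        assert frac <= 0.01

    def test_empty_dataset_rejected(self):
        model = build_model(small_config())
        with pytest.raises(ValueError):
            train(model, [], TrainHyperparams())


class TestSaveLoad:
    def test_round_trip_is_bit_exact(self, tmp_path, set1_scene):
        ds = generate_dataset(scene_specs("set1", 4, 8, (32, 32)))
        model = build_model(small_config(size=(32, 32)))
        train(model, ds, TrainHyperparams(epochs=1, batch_size=4, seed=0),
              stage_tag="ce")
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.stage_tag == "ce"
        assert loaded.training_manifest_hash == model.training_manifest_hash
        img = set1_scene.image[:32, :32]
        assert np.array_equal(predict_mask(loaded, img), predict_mask(model, img))
        for (ka, va), (kb, vb) in zip(
            model.net.state_dict().items(), loaded.net.state_dict().items()
        ):
            assert np.array_equal(va, vb)

    def test_pretrained_init_preserves_encoder_resets_head(self, tmp_path):
        ds = generate_dataset(scene_specs("set1", 4, 8, (32, 32)))
        model = build_model(small_config(size=(32, 32)))
        train(model, ds, TrainHyperparams(epochs=1, batch_size=4, seed=0),
              stage_tag="ce")
        path = tmp_path / "enc.npz"
        save_model(model, path)
        cfg = NetworkConfig(
            backbone="tiny", input_size=(32, 32), seed=4,
            pretrained_weights=str(path),
        )
        warm = build_model(cfg)
        assert np.array_equal(warm.net.stem.W, model.net.stem.W)
        assert not np.array_equal(warm.net.head.W, model.net.head.W)
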