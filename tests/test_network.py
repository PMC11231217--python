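"""Assembly, inference, training and parameter counting of the full network."""

import numpy as np
import pytest

from icnet.engine import BatchNorm, Conv2D
from icnet.network import (
    ModelConfig,
    build_model,
    count_parameters,
    load_model,
    predict,
    save_model,
    train,
)

TINY = ModelConfig(input_height=16, input_width=16, width_multiplier=0.05,
                   num_classes=4, seed=11)


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(TINY)


class TestBuildAndPredict:
    def test_output_shape_and_probability_normalization(self, tiny_model, rng):
        x = rng.normal(size=(2, 16, 16, 1))
        p = predict(tiny_model, x)
        assert p.shape == (2, 16, 16, 4)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert np.abs(p.sum(axis=-1) - 1.0).max() < 1e-5

    def test_bottleneck_spatial_size_is_input_over_16(self, tiny_model, rng):
        predict(tiny_model, rng.normal(size=(1, 16, 16, 1)))
        # the deepest transpose conv cached the gating features it upsampled
        _, h, w, _ = tiny_model.upconvs[0]._cache
        assert (h, w) == (1, 1)  # 16 / 2**4

    def test_inference_is_deterministic(self, tiny_model, rng):
        x = rng.normal(size=(1, 16, 16, 1))
        assert np.array_equal(predict(tiny_model, x), predict(tiny_model, x))

    def test_argmax_is_a_valid_label_volume(self, tiny_model, rng):
        labels = predict(tiny_model, rng.normal(size=(1, 16, 16, 1))).argmax(axis=-1)
        assert set(np.unique(labels)) <= {0, 1, 2, 3}

    def test_shape_mismatch_raises(self, tiny_model, rng):
        with pytest.raises(ValueError, match="expected input"):
            predict(tiny_model, rng.normal(size=(1, 32, 32, 1)))

    @pytest.mark.parametrize("kwargs", [
        {"input_height": 30, "input_width": 32},
        {"encoder_filters": (8, 16, 32)},
        {"num_classes": 1},
        {"width_multiplier": 0.0},
    ])
    def test_illegal_config_raises(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)


class TestGradientsAndTraining:
    def test_every_trainable_parameter_receives_gradient(self, rng):
        model = build_model(ModelConfig(input_height=16, input_width=16,
                                        width_multiplier=0.05, seed=3))
        x = rng.normal(size=(2, 16, 16, 1))
        t = np.eye(4)[rng.integers(0, 4, size=(2, 16, 16))]
        p = model.forward(x, training=True)
        for par in model.parameters():
            par.zero_grad()
        model.backward((p - t) / t[..., 0].size)
        for par in model.parameters():
            if par.trainable:
                assert np.abs(par.grad).max() > 0, f"zero gradient for {par.name}"

    def test_initial_loss_near_log_num_classes(self, rng):
        # an untrained head starts near the uniform prediction, where
        # cross-entropy on balanced labels is ln K
        model = build_model(ModelConfig(input_height=16, input_width=16,
                                        width_multiplier=0.05, num_classes=4,
                                        seed=5, epochs=1))
        x = rng.normal(size=(4, 16, 16, 1))
        labels = rng.permuted(np.repeat(np.arange(4), 4 * 16 * 16 // 4)).reshape(4, 16, 16)
        t = np.eye(4)[labels]
        history = train(model, [(x, t)])
        assert history[0]["loss"] == pytest.approx(np.log(4), rel=0.20)

    def test_training_is_seed_reproducible(self, rng):
        x = rng.normal(size=(2, 16, 16, 1))
        t = np.eye(4)[rng.integers(0, 4, size=(2, 16, 16))]
        losses = []
        for _ in range(2):
            cfg = ModelConfig(input_height=16, input_width=16,
                              width_multiplier=0.05, seed=21, epochs=1)
            history = train(build_model(cfg), [(x, t)], cfg)
            losses.append(history[0]["loss"])
        assert losses[0] == losses[1]

    def test_history_carries_monitoring_roster(self, rng):
        from icnet.network import HISTORY_ROSTER
        x = rng.normal(size=(2, 16, 16, 1))
        t = np.eye(4)[rng.integers(0, 4, size=(2, 16, 16))]
        cfg = ModelConfig(input_height=16, input_width=16,
                          width_multiplier=0.05, seed=2, epochs=2)
        history = train(build_model(cfg), [(x, t)], cfg)
        assert len(history) == 2
        for row in history:
            for name in HISTORY_ROSTER:
                assert np.isfinite(row[name]), name

    def test_empty_dataset_raises(self, tiny_model):
        with pytest.raises(ValueError, match="empty"):
            train(tiny_model, [])


class TestParameterCounting:
    def test_single_conv_layer(self):
        layer = Conv2D(1, 8, 3)
        assert sum(p.size for p in layer.parameters()) == 3 * 3 * 1 * 8 + 8

    def test_batchnorm_split(self):
        bn = BatchNorm(16)
        trainable = sum(p.size for p in bn.parameters() if p.trainable)
        frozen = sum(p.size for p in bn.parameters() if not p.trainable)
        assert (trainable, frozen) == (32, 32)

    def test_counts_match_closed_form_layer_sum(self):
        cfg = ModelConfig(input_height=32, input_width=32, width_multiplier=0.25)
        model = build_model(cfg)
        f = cfg.filters

        def conv(k, cin, cout):
            return k * k * cin * cout + cout

        expected = 0
        cin = cfg.in_channels
        for nf in f:  # encoder MA blocks: two 3x3 convs + BN scale/shift
            expected += conv(3, cin, nf) + conv(3, nf, nf) + 2 * nf
            cin = nf
        nf = f[4]  # FCN bottleneck: three branch convs + merge
        expected += conv(3, nf, nf) * 3 + conv(3, 3 * nf, nf)
        gating = nf
        for level in (4, 3, 2, 1):
            nf = f[level - 1]
            expected += conv(2, gating, nf)                      # transpose conv
            expected += conv(1, nf, nf) * 2 + conv(1, nf, 1)     # attention gate
            expected += conv(3, 2 * nf, nf) + conv(3, nf, nf) + 2 * nf  # decoder MA
            gating = nf
        expected += conv(1, f[0], cfg.num_classes)               # head
        counts = count_parameters(model)
        assert counts["trainable"] == expected
        # BN running stats are the only non-trainable parameters
        assert counts["non_trainable"] == 2 * sum(f) + 2 * sum(f[:4])

    def test_width_doubling_roughly_quadruples_parameters(self):
        small = count_parameters(build_model(
            ModelConfig(input_height=16, input_width=16, width_multiplier=0.25)))
        big = count_parameters(build_model(
            ModelConfig(input_height=16, input_width=16, width_multiplier=0.5)))
        ratio = big["trainable"] / small["trainable"]
        assert 3.0 < ratio < 5.0

    def test_counts_invariant_under_inference(self, tiny_model, rng):
        before = count_parameters(tiny_model)
        predict(tiny_model, rng.normal(size=(1, 16, 16, 1)))
        assert count_parameters(tiny_model) == before


def test_checkpoint_round_trip(tmp_path, rng):
    cfg = ModelConfig(input_height=16, input_width=16, width_multiplier=0.05, seed=4)
    model = build_model(cfg)
    x = rng.normal(size=(1, 16, 16, 1))
    save_model(model, tmp_path / "ckpt.pkl")
    restored = load_model(tmp_path / "ckpt.pkl")
    assert np.array_equal(predict(model, x), predict(restored, x))
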