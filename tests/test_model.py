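import numpy as np
import pytest

from nanosieve.errors import ValidationError
from nanosieve.model import (
    ModelConfig,
    build_model,
    integrated_gradients,
    load_checkpoint,
    parameter_bytes,
    save_checkpoint,
)

MODEL_SIZE_BUDGET_BYTES = 304 * 1024


def toy_config():
    return ModelConfig(stem_channels=2, stem_kernel=3, stem_stride=1,
                       n_layers=1, blocks_per_layer=1, block_stride=2,
                       block_kernel=3, n_classes=2, input_length=16)


class TestArchitecture:
    def test_default_fits_304kb_budget(self):
        net = build_model(seed=0)
        assert parameter_bytes(net) <= MODEL_SIZE_BUDGET_BYTES

    def test_channel_schedule_grows_by_half(self):
        assert ModelConfig().layer_channels() == [20, 30, 45, 68]

    def test_toy_parameter_count_matches_hand_sum(self):
        # stem conv 1*2*3 + stem BN 4*2
        # block (in 2, out 2, mid 1): conv1 2*1, bn1 4*1, conv2 1*1*3,
        #   bn2 4*1, conv3 1*2, bn3 4*2, proj 2*2 (stride 2), proj_bn 4*2
        # head: 2*2 weights + 2 bias
        hand = (6 + 8) + (2 + 4 + 3 + 4 + 2 + 8 + 4 + 8) + (4 + 2)
        net = build_model(toy_config(), seed=1)
        assert parameter_bytes(net) == 4 * hand

    def test_wider_stem_strictly_increases_storage(self):
        small = parameter_bytes(build_model(ModelConfig(), seed=0))
        big = parameter_bytes(build_model(ModelConfig(stem_channels=40), seed=0))
        assert big > small

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            build_model(ModelConfig(n_classes=1))

    def test_too_short_input_names_minimum(self):
        with pytest.raises(ValidationError, match=str(ModelConfig().total_stride())):
            build_model(ModelConfig(input_length=100))

    @pytest.mark.parametrize("length", [768, 1000, 3000, 5000])
    def test_trunk_length_matches_stride_arithmetic(self, length):
        net = build_model(ModelConfig(input_length=length), seed=0)
        L = (length + 2 * 9 - 19) // 3 + 1
        for _ in range(8):
            L = (L + 2 - 3) // 2 + 1
        assert net.trunk_output_length(length) == L
        probs = net.forward(np.zeros((1, length), dtype=np.float32))
        assert probs.shape == (1, 2)

    def test_build_determinism(self):
        a = build_model(ModelConfig(), seed=42)
        b = build_model(ModelConfig(), seed=42)
        assert a.parameter_inventory() == b.parameter_inventory()
        for k, v in a.state_dict().items():
            np.testing.assert_array_equal(v, b.state_dict()[k])


class TestForward:
    def test_probability_simplex_on_random_inputs(self, rng):
        net = build_model(ModelConfig(input_length=768), seed=0)
        x = rng.normal(size=(1000, 768)).astype(np.float32)
        p = net.forward(x)
        assert np.all(p >= 0) and np.all(p <= 1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_rows_give_identical_outputs(self, rng):
        net = build_model(ModelConfig(input_length=768), seed=0)
        x = rng.normal(size=768).astype(np.float32)
        p = net.forward(np.stack([x, x]))
        np.testing.assert_allclose(p[0], p[1], atol=1e-7)

    def test_zeroed_head_gives_uniform_probabilities(self, rng):
        net = build_model(ModelConfig(input_length=768), seed=0)
        net.fc.weight[:] = 0
        net.fc.bias[:] = 0
        p = net.forward(rng.normal(size=(3, 768)).astype(np.float32))
        np.testing.assert_allclose(p, 0.5, atol=1e-7)

    def test_wrong_window_length_rejected(self, rng):
        net = build_model(ModelConfig(), seed=0)
        with pytest.raises(ValidationError):
            net.forward(rng.normal(size=(2, 100)).astype(np.float32))


class _LinearSurrogate:
    """Duck-typed 1-layer linear scorer for closed-form attribution checks."""

    def __init__(self, weight):
        self.weight = np.asarray(weight, dtype=np.float32)

        class _Cfg:
            n_classes = weight.shape[0]
        self.config = _Cfg()

    def logits(self, x, training=False):
        x = np.atleast_2d(np.asarray(x, dtype=np.float32))
        self._x = x
        return x @ self.weight.T

    def backward(self, dlogits):
        return (dlogits @ self.weight)[:, None, :]


class TestIntegratedGradients:
    def test_zero_path_gives_zero_attributions(self, rng):
        net = build_model(ModelConfig(input_length=768), seed=0)
        x = rng.normal(size=768)
        attr = integrated_gradients(net, x, x.copy(), steps=4, target_class=1)
        np.testing.assert_array_equal(attr, 0.0)

    def test_completeness_within_one_percent(self, rng):
        net = build_model(seed=0)
        window = rng.normal(size=3000)
        baseline = np.zeros(3000)
        attr = integrated_gradients(net, window, baseline, steps=256,
                                    target_class=1)
        s_w = net.logits(window)[0, 1]
        s_b = net.logits(baseline)[0, 1]
        delta = s_w - s_b
        assert attr.sum() == pytest.approx(delta, rel=0.01)

    def test_exact_on_linear_model(self, rng):
        w = rng.normal(size=(2, 20))
        surrogate = _LinearSurrogate(w)
        window = rng.normal(size=20)
        baseline = rng.normal(size=20)
        attr = integrated_gradients(surrogate, window, baseline, steps=5,
                                    target_class=1)
        np.testing.assert_allclose(attr, w[1] * (window - baseline), rtol=1e-5)

    def test_mismatched_lengths_rejected(self, rng):
        net = build_model(ModelConfig(input_length=768), seed=0)
        with pytest.raises(ValidationError):
            integrated_gradients(net, rng.normal(size=768), rng.normal(size=99))


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, rng, tmp_path):
        net = build_model(ModelConfig(input_length=768), seed=5)
        x = rng.normal(size=(3, 768)).astype(np.float32)
        path = save_checkpoint(net, tmp_path / "m.npz")
        back = load_checkpoint(path)
        np.testing.assert_array_equal(net.forward(x), back.forward(x))
        assert back.config == net.config
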