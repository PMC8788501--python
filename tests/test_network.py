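"""Network assembly: shape ladder, prediction contract, checkpoints."""

import numpy as np
import pytest

from vertebox import nn
from vertebox.errors import ConfigurationError, InvalidInputError
from vertebox.losses import deep_supervision_loss, one_hot
from vertebox.network import (
    NetworkConfig, PredictionSet, build_vertebox, load_checkpoint,
    predict_labels, save_checkpoint,
)
from vertebox.nn import softmax

RNG = np.random.default_rng(61)

MINI = NetworkConfig(base_width=8, input_size=64)


def zero_all_gates(model):
    for attn in list(model.skip_attn) + [model.bottleneck_attn]:
        for _, p in attn.named_parameters():
            p.data = np.zeros_like(p.data)


@pytest.fixture(scope="module")
def mini_model():
    return build_vertebox(MINI, seed=0)


class TestConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            NetworkConfig(base_width=6)
        with pytest.raises(ConfigurationError):
            NetworkConfig(input_size=100)
        with pytest.raises(ConfigurationError):
            NetworkConfig(num_classes=1)

    def test_encoder_widths_double(self):
        assert NetworkConfig().encoder_widths == (64, 128, 256, 512, 1024)


class TestForward:
    def test_shape_ladder_miniature(self, mini_model):
        x = RNG.standard_normal((1, 1, 64, 64)).astype(np.float32)
        skips, bottleneck = mini_model.encoder_features(x)
        assert [s.shape for s in skips] == [
            (1, 8, 64, 64), (1, 16, 32, 32), (1, 32, 16, 16), (1, 64, 8, 8)]
        assert bottleneck.shape == (1, 128, 4, 4)

    def test_prediction_set_contract(self, mini_model):
        x = RNG.standard_normal((2, 1, 64, 64)).astype(np.float32)
        preds = mini_model(x)
        assert len(preds.aux) == 4
        for m in preds.maps():
            assert m.shape == (2, 2, 64, 64)
            assert np.all(np.isfinite(m.data))
        probs = softmax(nn.as_tensor(preds.final.data), axis=1).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_eval_mode_deterministic(self, mini_model):
        mini_model.eval()
        x = RNG.standard_normal((1, 1, 64, 64)).astype(np.float32)
        with nn.no_grad():
            a = mini_model(x).final.data
            b = mini_model(x).final.data
        mini_model.train()
        np.testing.assert_array_equal(a, b)

    def test_wrong_input_size_rejected(self, mini_model):
        with pytest.raises(InvalidInputError):
            mini_model(RNG.standard_normal((1, 1, 32, 32)).astype(np.float32))
        with pytest.raises(InvalidInputError):
            mini_model(RNG.standard_normal((1, 3, 64, 64)).astype(np.float32))

    def test_zero_gate_attention_matches_swapped_in_scaling(self):
        """Zeroed gates make each skip CAM a 0.5-scaling and the bottleneck
        dual module the exact identity; swapping those modules in reproduces
        the forward pass."""

        class HalfScale(nn.Module):
            def forward(self, x):
                return x * 0.5

        model = build_vertebox(MINI, seed=3)
        model.eval()
        zero_all_gates(model)
        x = RNG.standard_normal((1, 1, 64, 64)).astype(np.float32)
        with nn.no_grad():
            with_attn = model(x).final.data
        model.skip_attn = nn.ModuleList([HalfScale() for _ in range(4)])
        model.bottleneck_attn = nn.Identity()
        with nn.no_grad():
            swapped = model(x).final.data
        np.testing.assert_allclose(with_attn, swapped, atol=1e-5)

    def test_gradient_reaches_every_head(self, mini_model):
        x = RNG.standard_normal((1, 1, 64, 64)).astype(np.float32)
        y = one_hot(RNG.integers(0, 2, (1, 64, 64)), 2)
        mini_model.zero_grad()
        loss = deep_supervision_loss(y, mini_model(x))
        loss.backward()
        for name, p in mini_model.named_parameters():
            if name.startswith(("heads", "fuse")):
                assert p.grad is not None and np.any(p.grad), name


class TestPredictLabels:
    def test_uniform_winner(self):
        final = np.zeros((1, 2, 4, 4))
        final[:, 1] = 1.0
        assert np.all(predict_labels(PredictionSet([final] * 4, final)) == 1)

    def test_ties_go_to_background(self):
        final = np.ones((1, 2, 3, 3))
        assert np.all(predict_labels(final) == 0)

    def test_matches_per_pixel_argmax(self):
        final = RNG.standard_normal((2, 3, 5, 5))
        labels = predict_labels(final)
        for n in range(2):
            for i in range(5):
                for j in range(5):
                    assert labels[n, i, j] == int(np.argmax(final[n, :, i, j]))

    def test_only_final_map_is_used(self, mini_model):
        x = RNG.standard_normal((1, 1, 64, 64)).astype(np.float32)
        with nn.no_grad():
            preds = mini_model(x)
        flipped = PredictionSet([nn.Tensor(-m.data) for m in preds.aux], preds.final)
        np.testing.assert_array_equal(predict_labels(preds), predict_labels(flipped))


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, mini_model, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(mini_model, path, extra={"note": "round-trip"})
        loaded, extra = load_checkpoint(path)
        assert extra == {"note": "round-trip"}
        mini_model.eval()
        x = RNG.standard_normal((1, 1, 64, 64)).astype(np.float32)
        with nn.no_grad():
            np.testing.assert_array_equal(mini_model(x).final.data,
                                          loaded(x).final.data)
        mini_model.train()

    def test_version_mismatch_rejected(self, mini_model, tmp_path):
        import json
        path = tmp_path / "model.npz"
        save_checkpoint(mini_model, path)
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        meta["version"] = 99
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), np.uint8),
                 **state)
        with pytest.raises(InvalidInputError):
            load_checkpoint(path)


def test_parameter_count_matches_independent_tally(mini_model):
    """Total parameter count equals a hand tally over the state dict shapes."""
    tally = sum(int(np.prod(v.shape)) for k, v in mini_model.state_dict().items()
                if not k.endswith(("running_mean", "running_var")))
    assert mini_model.num_parameters() == tally
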