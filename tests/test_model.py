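"""Architecture tests: block semantics, shapes, parameter accounting.

The per-block parameter counts are closed-form consequences of the block
composition (all convolutions and projections carry biases, two
channel-axis layer normalisations per attention block); the counts for the
default geometry are asserted exactly in the acceptance suite.
"""

import numpy as np
import pytest

from fmha_ae.autodiff import Tensor
from fmha_ae.model import (
    ChannelMultiHeadSelfAttention,
    FeedForward,
    FMHAAutoencoder,
    FMHCADecoderBlock,
    FMHSAEncoderBlock,
    MHSAShortcutBlock,
    ModelConfig,
    MultiHeadCrossAttention,
    MultiHeadSelfAttention,
    Module,
    ResidualBlock,
    build_model,
    count_trainable_parameters,
)

RNG = np.random.default_rng


def _rng():
    return RNG(11)


DTYPE = np.float64


class TestModelConfig:
    def test_heads_must_divide_width(self):
        with pytest.raises(ValueError, match="divisible by heads"):
            ModelConfig(width=30, heads=4)

    def test_segment_length_must_match_depth(self):
        with pytest.raises(ValueError, match="2\\*\\*depth"):
            ModelConfig(width=32, depth=7, segment_length=64)

    def test_d_ff_defaults_to_four_times_width(self):
        assert ModelConfig(width=64).d_ff == 256
        assert ModelConfig(width=64, d_ff=100).d_ff == 100

    def test_bottleneck_length(self):
        assert ModelConfig().bottleneck_length == 8


class TestResidualBlock:
    def test_zero_weights_reduce_to_relu(self, rng):
        blk = ResidualBlock(4, 5, _rng(), DTYPE)
        for p in blk.parameters():
            p.data[:] = 0.0
        x = rng.normal(size=(2, 4, 16))
        out = blk(Tensor(x)).data
        np.testing.assert_allclose(out, np.maximum(x, 0.0), atol=1e-14)

    def test_shape_preserved(self, rng):
        blk = ResidualBlock(128, 5, _rng(), DTYPE)
        out = blk(Tensor(rng.normal(size=(1, 128, 64))))
        assert out.shape == (1, 128, 64)

    def test_parameter_count_closed_form(self):
        # two C->C convolutions of length 5 with biases
        blk = ResidualBlock(128, 5, _rng(), DTYPE)
        assert count_trainable_parameters(blk) == 2 * (128 * 128 * 5 + 128)


class TestAttention:
    def naive_mhsa(self, x, blk):
        """Three-nested-loop attention oracle (single batch element)."""
        h = blk.heads
        c = x.shape[1]
        dk = c // h
        q = x @ blk.wq.weight.data + blk.wq.bias.data
        k = x @ blk.wk.weight.data + blk.wk.bias.data
        v = x @ blk.wv.weight.data + blk.wv.bias.data
        out = np.zeros_like(x)
        for i in range(h):
            qi = q[:, i * dk : (i + 1) * dk]
            ki = k[:, i * dk : (i + 1) * dk]
            vi = v[:, i * dk : (i + 1) * dk]
            scores = np.zeros((x.shape[0], x.shape[0]))
            for a in range(x.shape[0]):
                for b in range(x.shape[0]):
                    scores[a, b] = qi[a] @ ki[b] / np.sqrt(dk)
            w = np.exp(scores - scores.max(axis=1, keepdims=True))
            w /= w.sum(axis=1, keepdims=True)
            out[:, i * dk : (i + 1) * dk] = w @ vi
        return out @ blk.wo.weight.data + blk.wo.bias.data

    def test_matches_loop_oracle(self, rng):
        blk = MultiHeadSelfAttention(8, 2, _rng(), DTYPE)
        x = rng.normal(size=(4, 8))
        got = blk(Tensor(x[None])).data[0]
        np.testing.assert_allclose(got, self.naive_mhsa(x, blk), atol=1e-10)

    def test_rows_stochastic(self, rng):
        blk = MultiHeadSelfAttention(16, 4, _rng(), DTYPE)
        blk.record_attention = True
        blk(Tensor(rng.normal(size=(3, 10, 16))))
        sums = blk.last_attention.sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_single_token_attention_is_identity_weight(self, rng):
        blk = MultiHeadSelfAttention(8, 2, _rng(), DTYPE)
        blk.record_attention = True
        x = rng.normal(size=(1, 1, 8))
        out = blk(Tensor(x))
        np.testing.assert_allclose(blk.last_attention, 1.0)
        # with a single token the value path fully determines the output
        v = x[0] @ blk.wv.weight.data + blk.wv.bias.data
        expected = v @ blk.wo.weight.data + blk.wo.bias.data
        np.testing.assert_allclose(out.data[0], expected, atol=1e-12)

    def test_rejects_indivisible_heads(self):
        with pytest.raises(ValueError, match="divisible"):
            MultiHeadSelfAttention(10, 4, _rng(), DTYPE)


class TestCrossAttention:
    def naive_mhca(self, f, e, blk):
        h = blk.heads
        dk = f.shape[1] // h
        q = f @ blk.wq.weight.data + blk.wq.bias.data
        k = e @ blk.wk.weight.data + blk.wk.bias.data
        v = e @ blk.wv.weight.data + blk.wv.bias.data
        out = np.zeros_like(f)
        for i in range(h):
            qi, ki, vi = (
                m[:, i * dk : (i + 1) * dk] for m in (q, k, v)
            )
            scores = qi @ ki.T / np.sqrt(dk)
            w = np.exp(scores - scores.max(axis=1, keepdims=True))
            w /= w.sum(axis=1, keepdims=True)
            out[:, i * dk : (i + 1) * dk] = w @ vi
        return out @ blk.wo.weight.data + blk.wo.bias.data

    def test_matches_loop_oracle(self, rng):
        blk = MultiHeadCrossAttention(8, 2, _rng(), DTYPE)
        f = rng.normal(size=(4, 8))
        e = rng.normal(size=(2, 8))
        got = blk(Tensor(f[None]), Tensor(e[None])).data[0]
        np.testing.assert_allclose(got, self.naive_mhca(f, e, blk), atol=1e-10)

    def test_attention_map_shape_and_stochasticity(self, rng):
        blk = MultiHeadCrossAttention(8, 4, _rng(), DTYPE)
        blk.record_attention = True
        blk(Tensor(rng.normal(size=(2, 6, 8))), Tensor(rng.normal(size=(2, 3, 8))))
        assert blk.last_attention.shape == (2, 4, 6, 3)
        np.testing.assert_allclose(blk.last_attention.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_key_gives_unit_weights(self, rng):
        blk = MultiHeadCrossAttention(8, 2, _rng(), DTYPE)
        blk.record_attention = True
        blk(Tensor(rng.normal(size=(1, 5, 8))), Tensor(rng.normal(size=(1, 1, 8))))
        np.testing.assert_allclose(blk.last_attention, 1.0)

    def test_rejects_channel_mismatch(self, rng):
        blk = MultiHeadCrossAttention(8, 2, _rng(), DTYPE)
        with pytest.raises(ValueError, match="channel mismatch"):
            blk(Tensor(rng.normal(size=(1, 4, 8))), Tensor(rng.normal(size=(1, 4, 6))))


class TestChannelAttention:
    def test_attention_between_channels_rows_stochastic(self, rng):
        blk = ChannelMultiHeadSelfAttention(16, 4, _rng(), DTYPE)
        blk(Tensor(rng.normal(size=(2, 12, 16))))
        assert blk.last_attention.shape == (2, 4, 4, 4)  # d_k x d_k maps
        np.testing.assert_allclose(blk.last_attention.sum(axis=-1), 1.0, atol=1e-6)

    def test_parameter_count_independent_of_length(self):
        a = MHSAShortcutBlock(128, 4, 512, _rng(), DTYPE)
        n = count_trainable_parameters(a)
        # same block applied at two very different sequence lengths
        for length in (512, 16):
            out = a(Tensor(np.random.default_rng(0).normal(size=(1, 128, length))))
            assert out.shape == (1, 128, length)
        assert n == count_trainable_parameters(a)

    def test_shortcut_count_closed_form(self):
        blk = MHSAShortcutBlock(128, 4, 512, _rng(), DTYPE)
        proj = 4 * (128 * 128 + 128)
        ffn = (128 * 512 + 512) + (512 * 128 + 128)
        norms = 2 * (128 + 128)
        assert count_trainable_parameters(blk) == proj + ffn + norms == 198_272


class TestFFN:
    def test_constant_output_with_zero_weights(self, rng):
        ffn = FeedForward(8, 32, _rng(), DTYPE)
        for p in (ffn.lin1.weight, ffn.lin1.bias, ffn.lin2.weight):
            p.data[:] = 0.0
        ffn.lin2.bias.data[:] = 3.5
        out = ffn(Tensor(rng.normal(size=(2, 5, 8))))
        np.testing.assert_allclose(out.data, 3.5)

    def test_matches_per_position_loop(self, rng):
        ffn = FeedForward(128, 512, _rng(), DTYPE)
        x = rng.normal(size=(3, 128))
        got = ffn(Tensor(x[None])).data[0]
        for i in range(3):
            h = np.maximum(x[i] @ ffn.lin1.weight.data + ffn.lin1.bias.data, 0)
            expect = h @ ffn.lin2.weight.data + ffn.lin2.bias.data
            np.testing.assert_allclose(got[i], expect, atol=1e-10)

    def test_parameter_count_closed_form(self):
        ffn = FeedForward(128, 512, _rng(), DTYPE)
        assert count_trainable_parameters(ffn) == (128 * 512 + 512) + (
            512 * 128 + 128
        ) == 131_712


class TestEncoderDecoderBlocks:
    def test_encoder_halves_length(self, rng):
        blk = FMHSAEncoderBlock(16, 4, 64, 5, _rng(), DTYPE)
        out = blk(Tensor(rng.normal(size=(2, 16, 32))))
        assert out.shape == (2, 16, 16)

    def test_encoder_rejects_odd_length(self, rng):
        blk = FMHSAEncoderBlock(16, 4, 64, 5, _rng(), DTYPE)
        with pytest.raises(ValueError, match="even feature length"):
            blk(Tensor(rng.normal(size=(1, 16, 7))))

    def test_decoder_doubles_length(self, rng):
        blk = FMHCADecoderBlock(16, 4, 64, 5, _rng(), DTYPE)
        e = Tensor(rng.normal(size=(2, 4, 16)))
        out = blk(Tensor(rng.normal(size=(2, 16, 8))), e)
        assert out.shape == (2, 16, 16)

    def test_decoder_rejects_bottleneck_channel_mismatch(self, rng):
        blk = FMHCADecoderBlock(16, 4, 64, 5, _rng(), DTYPE)
        e = Tensor(rng.normal(size=(2, 4, 12)))
        with pytest.raises(ValueError, match="channel mismatch"):
            blk(Tensor(rng.normal(size=(2, 16, 8))), e)


class TestFullModel:
    def test_forward_shape_and_finiteness(self, tiny_model, rng):
        x = Tensor(rng.normal(size=(2, 1, 64)))
        out = tiny_model(x)
        assert out.shape == (2, 1, 64)
        assert np.all(np.isfinite(out.data))

    def test_encoder_stage_lengths(self, tiny_model, rng):
        x = tiny_model.input_layer(Tensor(rng.normal(size=(1, 1, 64))))
        lengths = []
        for enc in tiny_model.encoders:
            x = enc(x)
            lengths.append(x.shape[-1])
        assert lengths == [32, 16, 8]

    def test_deterministic_forward_and_construction(self, rng):
        cfg = ModelConfig(width=16, depth=2, heads=4, segment_length=32, seed=3)
        x = rng.normal(size=(1, 32))
        out1 = build_model(cfg).denoise(x)
        out2 = build_model(cfg).denoise(x)
        np.testing.assert_array_equal(out1, out2)

    def test_gradient_reaches_every_parameter(self, tiny_model, rng):
        x = Tensor(rng.normal(size=(2, 1, 64)))
        target = Tensor(rng.normal(size=(2, 1, 64)))
        tiny_model.zero_grad()
        loss = (tiny_model(x) - target).square().mean()
        loss.backward()
        for name, p in tiny_model.named_parameters():
            assert p.grad is not None, f"no gradient for {name}"
            assert np.any(p.grad != 0.0), f"all-zero gradient for {name}"

    def test_zero_module_counts_zero(self):
        assert count_trainable_parameters(Module()) == 0

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = ModelConfig(width=16, depth=2, heads=4, segment_length=32, seed=5)
        model = build_model(cfg)
        x = rng.normal(size=(3, 32))
        before = model.denoise(x)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = FMHAAutoencoder.load(path)
        np.testing.assert_array_equal(loaded.denoise(x), before)
        assert loaded.config == model.config

    def test_denoise_rejects_wrong_length(self, tiny_model):
        with pytest.raises(ValueError, match="length 64"):
            tiny_model.denoise(np.zeros(100))
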