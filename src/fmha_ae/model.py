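"""Feature-shuffle multi-head attention autoencoder (FMHA-AE).

A 1-D denoising autoencoder for single-lead ECG segments.  The encoder
halves the temporal length at every stage by de-interleaving samples into
channels (feature unshuffle) followed by a point-wise convolution, then
applies multi-head self-attention over time steps; the decoder mirrors this
with channel-doubling point-wise convolution + feature shuffle and
multi-head *cross*-attention against the encoder bottleneck.  Shortcut
blocks between matching encoder/decoder resolutions apply multi-head
attention over the *channel* axis and are merged by element-wise addition.

Default geometry: 1x1024 input, width 128, seven encoder stages
(1024 -> 8), six shortcuts, seven decoder stages (8 -> 1024), 1x1024 output.

Block composition (normative for this package, chosen so that every block's
trainable-parameter count is internally consistent):

* input layer   = 1x1 conv (1 -> C) + residual block
* encoder block = residual block -> feature unshuffle -> 1x1 conv (2C -> C)
                  -> MHSA (+res, post-LN) -> FFN (+res, post-LN)
* shortcut      = channel-MHSA (+res, post-LN) -> FFN (+res, post-LN)
* decoder block = residual block -> 1x1 conv (C -> 2C) -> feature shuffle
                  -> MHCA vs bottleneck (+res, post-LN) -> FFN (+res, post-LN)
* output layer  = residual block + 1x1 conv (C -> 1)

All convolutions and linear projections carry biases; layer normalisation
acts over the channel axis; there is no positional encoding.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Iterator, Optional

import numpy as np

from .autodiff import (
    Tensor,
    conv1d,
    layer_norm,
    matmul,
    relu,
    scaled_dot_attention,
    softmax,
)

__all__ = [
    "ModelConfig",
    "Module",
    "ResidualBlock",
    "FeedForward",
    "MultiHeadSelfAttention",
    "ChannelMultiHeadSelfAttention",
    "MultiHeadCrossAttention",
    "FMHSAEncoderBlock",
    "MHSAShortcutBlock",
    "FMHCADecoderBlock",
    "FMHAAutoencoder",
    "build_model",
    "count_trainable_parameters",
]

CHECKPOINT_VERSION = 1


@dataclasses.dataclass
class ModelConfig:
    """Geometry and initialisation of an FMHA-AE network.

    Parameters
    ----------
    width : channels C after input expansion.
    depth : number of encoder (= decoder) stages; there are depth-1 shortcuts.
    heads : attention heads h; ``width`` must divide evenly into them.
    d_ff : feed-forward hidden width; defaults to ``4 * width``.
    kernel : residual-block convolution length (padding = kernel // 2).
    segment_length : input length; must be divisible by ``2 ** depth``.
    seed : weight-initialisation seed.
    dtype : numpy dtype name for weights and activations.
    """

    width: int = 128
    depth: int = 7
    heads: int = 4
    d_ff: Optional[int] = None
    kernel: int = 5
    segment_length: int = 1024
    seed: int = 0
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.d_ff is None:
            self.d_ff = 4 * self.width
        if self.width < 1 or self.depth < 1 or self.heads < 1:
            raise ValueError("width, depth and heads must be positive")
        if self.width % self.heads != 0:
            raise ValueError(
                f"width must be divisible by heads (d_k = C/h): "
                f"got width={self.width}, heads={self.heads}"
            )
        if self.segment_length % (2**self.depth) != 0:
            raise ValueError(
                f"segment_length must be divisible by 2**depth: "
                f"got segment_length={self.segment_length}, depth={self.depth}"
            )
        if self.kernel % 2 != 1:
            raise ValueError(f"kernel must be odd, got {self.kernel}")

    @property
    def bottleneck_length(self) -> int:
        return self.segment_length // (2**self.depth)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# module machinery


class Module:
    """Base class: tracks parameters via attribute introspection."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{path}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def count_trainable_parameters(module: Module) -> int:
    """Exact number of trainable scalars in ``module`` (biases included)."""
    return sum(p.data.size for p in module.parameters())


def _uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> Tensor:
    bound = 1.0 / math.sqrt(fan_in)
    return Tensor(
        rng.uniform(-bound, bound, size=shape).astype(dtype), requires_grad=True
    )


class Conv1d(Module):
    """1-D convolution, stride 1, symmetric zero padding, with bias."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng, dtype):
        self.padding = kernel // 2
        self.weight = _uniform(rng, (c_out, c_in, kernel), c_in * kernel, dtype)
        self.bias = _uniform(rng, (c_out,), c_in * kernel, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.padding)


class Linear(Module):
    """Token-side affine map ``x @ W + b`` for x of shape (..., c_in)."""

    def __init__(self, c_in: int, c_out: int, rng, dtype):
        self.weight = _uniform(rng, (c_in, c_out), c_in, dtype)
        self.bias = _uniform(rng, (c_out,), c_in, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        # flatten batch axes into one GEMM: much faster than a strided
        # batched matmul, and the weight gradient needs no reduction
        shape = x.shape
        if x.ndim > 2:
            x = x.reshape(-1, shape[-1])
        y = matmul(x, self.weight) + self.bias
        if len(shape) > 2:
            y = y.reshape(*shape[:-1], y.shape[-1])
        return y


class LayerNorm(Module):
    """Normalisation over the channel (last) axis with learned gain/bias."""

    def __init__(self, c: int, dtype):
        self.weight = Tensor(np.ones(c, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(c, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.weight, self.bias)


class ResidualBlock(Module):
    """y = ReLU(conv2(ReLU(conv1(x))) + x), both convolutions C -> C."""

    def __init__(self, c: int, kernel: int, rng, dtype):
        self.conv1 = Conv1d(c, c, kernel, rng, dtype)
        self.conv2 = Conv1d(c, c, kernel, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return relu(self.conv2(relu(self.conv1(x))) + x)


class FeedForward(Module):
    """Position-wise FFN(X) = max(0, X W1 + b1) W2 + b2."""

    def __init__(self, c: int, d_ff: int, rng, dtype):
        self.lin1 = Linear(c, d_ff, rng, dtype)
        self.lin2 = Linear(d_ff, c, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(relu(self.lin1(x)))


def _split_heads(x: Tensor, h: int) -> Tensor:
    b, l, c = x.shape
    return x.reshape(b, l, h, c // h).transpose(0, 2, 1, 3)  # (B, h, L, d_k)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, l, dk = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, l, h * dk)


class MultiHeadSelfAttention(Module):
    """Time-step attention: tokens are the L samples, dims the C channels.

    Per head i: head_i = softmax(Q_i K_i^T / sqrt(d_k)) V_i with the
    attention map of shape L x L; heads are concatenated and projected by
    W_O.  Exposes the last attention map on ``last_attention`` for
    inspection (not part of the autodiff graph).
    """

    def __init__(self, c: int, h: int, rng, dtype):
        if c % h != 0:
            raise ValueError(f"channels ({c}) not divisible by heads ({h})")
        self.heads = h
        self.wq = Linear(c, c, rng, dtype)
        self.wk = Linear(c, c, rng, dtype)
        self.wv = Linear(c, c, rng, dtype)
        self.wo = Linear(c, c, rng, dtype)
        self.record_attention = False  # keep last maps only when asked
        self.last_attention: Optional[np.ndarray] = None

    def __call__(self, x: Tensor) -> Tensor:
        dk = x.shape[-1] // self.heads
        q = _split_heads(self.wq(x), self.heads)
        k = _split_heads(self.wk(x), self.heads)
        v = _split_heads(self.wv(x), self.heads)
        heads = scaled_dot_attention(q, k, v, 1.0 / math.sqrt(dk))
        if self.record_attention:
            self.last_attention = heads.attention_maps
        return self.wo(_merge_heads(heads))


class MultiHeadCrossAttention(Module):
    """Cross-attention: queries from the decoder path F, keys/values from
    the encoder bottleneck E; attention maps are F_len x E_len."""

    def __init__(self, c: int, h: int, rng, dtype):
        if c % h != 0:
            raise ValueError(f"channels ({c}) not divisible by heads ({h})")
        self.heads = h
        self.wq = Linear(c, c, rng, dtype)
        self.wk = Linear(c, c, rng, dtype)
        self.wv = Linear(c, c, rng, dtype)
        self.wo = Linear(c, c, rng, dtype)
        self.record_attention = False  # keep last maps only when asked
        self.last_attention: Optional[np.ndarray] = None

    def __call__(self, f: Tensor, e: Tensor) -> Tensor:
        if f.shape[-1] != e.shape[-1]:
            raise ValueError(
                f"cross-attention channel mismatch: decoder path has "
                f"{f.shape[-1]} channels, encoder memory has {e.shape[-1]}"
            )
        dk = f.shape[-1] // self.heads
        q = _split_heads(self.wq(f), self.heads)
        k = _split_heads(self.wk(e), self.heads)
        v = _split_heads(self.wv(e), self.heads)
        heads = scaled_dot_attention(q, k, v, 1.0 / math.sqrt(dk))
        if self.record_attention:
            self.last_attention = heads.attention_maps
        return self.wo(_merge_heads(heads))


class ChannelMultiHeadSelfAttention(Module):
    """Channel-correlation attention used by the shortcut blocks.

    Projections are identical to time-step attention (C x C weights on the
    channel axis, so the parameter count is independent of sequence
    length), but the attention map is computed *between channels*:
    A_i = softmax(Q_i^T K_i / sqrt(L)) of shape d_k x d_k, and
    head_i = V_i A_i.
    """

    def __init__(self, c: int, h: int, rng, dtype):
        if c % h != 0:
            raise ValueError(f"channels ({c}) not divisible by heads ({h})")
        self.heads = h
        self.wq = Linear(c, c, rng, dtype)
        self.wk = Linear(c, c, rng, dtype)
        self.wv = Linear(c, c, rng, dtype)
        self.wo = Linear(c, c, rng, dtype)
        self.record_attention = False  # keep last maps only when asked
        self.last_attention: Optional[np.ndarray] = None

    def __call__(self, x: Tensor) -> Tensor:
        length = x.shape[-2]
        q = _split_heads(self.wq(x), self.heads) * (
            1.0 / math.sqrt(length)
        )  # (B, h, L, d_k)
        k = _split_heads(self.wk(x), self.heads)
        v = _split_heads(self.wv(x), self.heads)
        attn = softmax(matmul(q.transpose(0, 1, 3, 2), k))
        # (B, h, d_k, d_k), rows sum to 1: tiny, so always kept
        self.last_attention = attn.data
        return self.wo(_merge_heads(matmul(v, attn)))


# ---------------------------------------------------------------------------
# feature (un)shuffle on batched autodiff tensors


def _unshuffle_t(x: Tensor) -> Tensor:
    b, c, length = x.shape
    return x.reshape(b, c, length // 2, 2).transpose(0, 1, 3, 2).reshape(
        b, 2 * c, length // 2
    )


def _shuffle_t(x: Tensor) -> Tensor:
    b, c2, half = x.shape
    return x.reshape(b, c2 // 2, 2, half).transpose(0, 1, 3, 2).reshape(
        b, c2 // 2, 2 * half
    )


def _to_tokens(x: Tensor) -> Tensor:
    return x.transpose(0, 2, 1)  # (B, C, L) -> (B, L, C)


def _to_channels(x: Tensor) -> Tensor:
    return x.transpose(0, 2, 1)  # (B, L, C) -> (B, C, L)


class FMHSAEncoderBlock(Module):
    """One encoder stage: C x L -> C x L/2.

    residual block -> feature unshuffle (C -> 2C, L -> L/2) -> point-wise
    conv (2C -> C) -> MHSA with residual connection and post-LN -> FFN with
    residual connection and post-LN.
    """

    def __init__(self, c: int, h: int, d_ff: int, kernel: int, rng, dtype):
        self.res = ResidualBlock(c, kernel, rng, dtype)
        self.pw = Conv1d(2 * c, c, 1, rng, dtype)
        self.attn = MultiHeadSelfAttention(c, h, rng, dtype)
        self.ln1 = LayerNorm(c, dtype)
        self.ffn = FeedForward(c, d_ff, rng, dtype)
        self.ln2 = LayerNorm(c, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] % 2 != 0:
            raise ValueError(
                f"encoder stage needs an even feature length, got {x.shape[-1]}"
            )
        y = self.pw(_unshuffle_t(self.res(x)))
        t = _to_tokens(y)
        t = self.ln1(t + self.attn(t))
        t = self.ln2(t + self.ffn(t))
        return _to_channels(t)


class MHSAShortcutBlock(Module):
    """Shortcut stage: channel attention + FFN, shape-preserving."""

    def __init__(self, c: int, h: int, d_ff: int, rng, dtype):
        self.attn = ChannelMultiHeadSelfAttention(c, h, rng, dtype)
        self.ln1 = LayerNorm(c, dtype)
        self.ffn = FeedForward(c, d_ff, rng, dtype)
        self.ln2 = LayerNorm(c, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        t = _to_tokens(x)
        t = self.ln1(t + self.attn(t))
        t = self.ln2(t + self.ffn(t))
        return _to_channels(t)


class FMHCADecoderBlock(Module):
    """One decoder stage: C x L -> C x 2L, cross-attending to the bottleneck.

    residual block -> point-wise conv (C -> 2C) -> feature shuffle
    (2C -> C, L -> 2L) -> MHCA against the encoder bottleneck with residual
    connection and post-LN -> FFN with residual connection and post-LN.
    """

    def __init__(self, c: int, h: int, d_ff: int, kernel: int, rng, dtype):
        self.res = ResidualBlock(c, kernel, rng, dtype)
        self.pw = Conv1d(c, 2 * c, 1, rng, dtype)
        self.attn = MultiHeadCrossAttention(c, h, rng, dtype)
        self.ln1 = LayerNorm(c, dtype)
        self.ffn = FeedForward(c, d_ff, rng, dtype)
        self.ln2 = LayerNorm(c, dtype)

    def __call__(self, x: Tensor, e_tokens: Tensor) -> Tensor:
        y = _shuffle_t(self.pw(self.res(x)))
        t = _to_tokens(y)
        t = self.ln1(t + self.attn(t, e_tokens))
        t = self.ln2(t + self.ffn(t))
        return _to_channels(t)


class InputLayer(Module):
    """1x1 conv expanding 1 -> C channels, then one residual block."""

    def __init__(self, c: int, kernel: int, rng, dtype):
        self.pw = Conv1d(1, c, 1, rng, dtype)
        self.res = ResidualBlock(c, kernel, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.res(self.pw(x))


class OutputLayer(Module):
    """One residual block, then a 1x1 conv collapsing C -> 1 channel."""

    def __init__(self, c: int, kernel: int, rng, dtype):
        self.res = ResidualBlock(c, kernel, rng, dtype)
        self.pw = Conv1d(c, 1, 1, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.pw(self.res(x))


class FMHAAutoencoder(Module):
    """The assembled network: 1 x L in, 1 x L out.

    Encoder stage i produces length L / 2**i; stages 1 .. depth-1 feed
    shortcut blocks whose outputs are added element-wise to the decoder
    path at the matching resolution (the bottleneck-consuming decoder stage
    receives no shortcut).  Every decoder stage cross-attends to the final
    encoder output (the bottleneck).
    """

    def __init__(self, config: ModelConfig):
        config = dataclasses.replace(config)  # defensive copy
        self.config = config
        c, h, d_ff, k = config.width, config.heads, config.d_ff, config.kernel
        dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        self.input_layer = InputLayer(c, k, rng, dtype)
        self.encoders = [
            FMHSAEncoderBlock(c, h, d_ff, k, rng, dtype)
            for _ in range(config.depth)
        ]
        self.shortcuts = [
            MHSAShortcutBlock(c, h, d_ff, rng, dtype)
            for _ in range(config.depth - 1)
        ]
        self.decoders = [
            FMHCADecoderBlock(c, h, d_ff, k, rng, dtype)
            for _ in range(config.depth)
        ]
        self.output_layer = OutputLayer(c, k, rng, dtype)

    # -- forward -------------------------------------------------------------
    def __call__(self, x: Tensor) -> Tensor:
        d = self.input_layer(x)
        enc_outputs = []
        for enc in self.encoders:
            d = enc(d)
            enc_outputs.append(d)
        bottleneck_tokens = _to_tokens(enc_outputs[-1])
        shortcut_out = [
            sc(e) for sc, e in zip(self.shortcuts, enc_outputs[:-1])
        ]
        d = enc_outputs[-1]
        # decoder stage j consumes length L / 2**j, j = depth .. 1
        for j in range(self.config.depth, 0, -1):
            d = self.decoders[j - 1](d, bottleneck_tokens)
            if j - 2 >= 0:  # add shortcut at the resolution the next stage consumes
                d = d + shortcut_out[j - 2]
        return self.output_layer(d)

    def denoise(self, signals: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Run inference on an (n, L) or (L,) array of noisy segments."""
        arr = np.asarray(signals, dtype=self.config.dtype)
        single = arr.ndim == 1
        if single:
            arr = arr[None, :]
        if arr.shape[1] != self.config.segment_length:
            raise ValueError(
                f"expected segments of length {self.config.segment_length}, "
                f"got {arr.shape[1]}"
            )
        params = list(self.parameters())
        flags = [p.requires_grad for p in params]
        for p in params:
            p.requires_grad = False
        try:
            chunks = []
            for lo in range(0, arr.shape[0], batch_size):
                x = Tensor(arr[lo : lo + batch_size, None, :])
                chunks.append(self(x).data[:, 0, :])
            out = np.concatenate(chunks, axis=0)
        finally:
            for p, f in zip(params, flags):
                p.requires_grad = f
        return out[0] if single else out

    # -- serialization -------------------------------------------------------
    def save(self, path) -> None:
        """Write a versioned checkpoint (.npz: config JSON + weights)."""
        arrays = {f"param:{n}": p.data for n, p in self.named_parameters()}
        header = json.dumps(
            {"format_version": CHECKPOINT_VERSION, "config": self.config.to_dict()}
        )
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "FMHAAutoencoder":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            if header.get("format_version") != CHECKPOINT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version {header.get('format_version')}"
                )
            model = cls(ModelConfig(**header["config"]))
            for name, p in model.named_parameters():
                stored = data[f"param:{name}"]
                if stored.shape != p.data.shape:
                    raise ValueError(f"checkpoint shape mismatch for {name}")
                p.data = stored.astype(p.data.dtype)
        return model


def build_model(config: ModelConfig) -> FMHAAutoencoder:
    """Construct an FMHA-AE network from a validated configuration."""
    return FMHAAutoencoder(config)
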