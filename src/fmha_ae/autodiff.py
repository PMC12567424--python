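"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network in :mod:`fmha_ae.model` needs a small, closed set of
differentiable primitives: broadcast add, elementwise multiply/subtract,
batched matmul, reshape/transpose, ReLU, row softmax, channel layer
normalisation, same-length 1-D convolution, and mean reduction.  Each
primitive records a backward closure on a :class:`Tensor`; ``backward()``
runs them in reverse topological order.  All heavy lifting stays inside
numpy/BLAS (the convolution is an im2col matmul), so batched training is
vectorised end to end.

Gradients accumulate into ``Tensor.grad``; ``requires_grad`` is inferred
from parents, so constants cost nothing.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from . import _kernels

__all__ = ["Tensor", "relu", "softmax", "layer_norm", "conv1d", "matmul"]


def _tune_allocator() -> None:
    """Keep large activation buffers on the heap so glibc reuses them.

    Training repeatedly allocates and frees attention-map-sized arrays;
    with the default mmap threshold every cycle pays an mmap/munmap plus
    page faults.  Best effort: silently does nothing off glibc/Linux.
    """
    try:
        import ctypes

        libc = ctypes.CDLL("libc.so.6", use_errno=True)
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
    except (OSError, AttributeError):  # pragma: no cover
        pass


_tune_allocator()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 stretched by broadcasting
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = (
        "data", "grad", "requires_grad", "_backward", "_parents",
        "_grad_owned", "attention_maps",
    )

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = backward
        self._parents = parents
        self._grad_owned = False
        self.attention_maps: Optional[np.ndarray] = None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        # First contribution adopts the incoming array without copying; a
        # second contribution allocates (the adopted array may be shared
        # with a sibling branch, so it must never be mutated in place).
        if self.grad is None:
            if grad.dtype != self.data.dtype:
                grad = grad.astype(self.data.dtype)
                self._grad_owned = True
            else:
                self._grad_owned = False
            self.grad = grad
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other, like=self.data)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, req, (self, other), backward)

    def __sub__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other, like=self.data)
        out_data = self.data - other.data
        req = self.requires_grad or other.requires_grad

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g, other.data.shape))

        return Tensor(out_data, req, (self, other), backward)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other, like=self.data)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, req, (self, other), backward)

    __rmul__ = __mul__

    def reshape(self, *shape: int) -> "Tensor":
        out_data = self.data.reshape(*shape)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def transpose(self, *axes: int) -> "Tensor":
        out_data = np.ascontiguousarray(self.data.transpose(*axes))
        inv = np.argsort(axes)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.transpose(*inv))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def mean(self) -> "Tensor":
        out_data = np.asarray(self.data.mean())
        n = self.data.size

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, g / n))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def square(self) -> "Tensor":
        return self * self

    # -- backprop driver ------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (7+7 stages of sub-ops)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node._parents:  # free intermediate grads eagerly
                    node.grad = None


def _as_tensor(x, like: Optional[np.ndarray] = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    # match the companion's dtype so python-float scalars never promote
    # a float32 graph to float64
    dtype = like.dtype if like is not None else None
    return Tensor(np.asarray(x, dtype=dtype))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product ``a @ b`` with broadcasting over batch axes."""
    out_data = a.data @ b.data
    req = a.requires_grad or b.requires_grad

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor(out_data, req, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * (out_data > 0))

    return Tensor(out_data, x.requires_grad, (x,), backward)


def softmax(x: Tensor) -> Tensor:
    """Softmax along the last axis; rows sum to one.

    Attention score arrays dominate the network's memory traffic, so both
    passes run through fused row-wise kernels.
    """
    shape = x.data.shape
    n = shape[-1]
    s2 = _kernels.softmax_fwd(
        np.ascontiguousarray(x.data).reshape(-1, n)
    )
    s = s2.reshape(shape)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            out = _kernels.softmax_bwd(
                np.ascontiguousarray(g).reshape(-1, n), s2
            )
            x._accumulate(out.reshape(shape))

    return Tensor(s, x.requires_grad, (x,), backward)


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise the last axis to zero mean / unit variance, then affine."""
    shape = x.data.shape
    n = shape[-1]
    eps = np.asarray(eps, dtype=x.data.dtype)[()]
    out2, xhat, invs = _kernels.layernorm_fwd(
        np.ascontiguousarray(x.data).reshape(-1, n),
        weight.data, bias.data, eps,
    )
    req = x.requires_grad or weight.requires_grad or bias.requires_grad

    def backward(g: np.ndarray) -> None:
        gx, gw, gb = _kernels.layernorm_bwd(
            np.ascontiguousarray(g).reshape(-1, n), xhat, invs, weight.data
        )
        if weight.requires_grad:
            weight._accumulate(gw)
        if bias.requires_grad:
            bias._accumulate(gb)
        if x.requires_grad:
            x._accumulate(gx.reshape(shape))

    return Tensor(out2.reshape(shape), req, (x, weight, bias), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, padding: int) -> Tensor:
    """Same-channel-layout 1-D convolution.

    ``x``: (B, C_in, L); ``weight``: (C_out, C_in, K); ``bias``: (C_out,).
    Zero padding of ``padding`` on both ends; stride 1.  Realised as one
    full-width GEMM per tap on a channel-major layout, which avoids the
    large im2col scratch array entirely.
    """
    b_sz, c_in, length = x.data.shape
    c_out, c_in_w, k = weight.data.shape
    if c_in != c_in_w:
        raise ValueError(
            f"conv1d channel mismatch: input has {c_in} channels, "
            f"weights expect {c_in_w}"
        )
    l_pad = length + 2 * padding
    l_out = l_pad - k + 1
    dtype = x.data.dtype
    # channel-major padded copy: (C_in, B, L_pad)
    xp = np.zeros((c_in, b_sz, l_pad), dtype=dtype)
    xp[:, :, padding : padding + length] = x.data.transpose(1, 0, 2)
    xt = xp.reshape(c_in, b_sz * l_pad)
    if k == 1:
        cols = xt  # l_out == l_pad: already the im2col matrix
    else:
        # explicit im2col in channel-major order: row (c*K + k) holds the
        # k-shifted copy of channel c; one GEMM then does the whole layer
        cols = np.empty((c_in * k, b_sz * l_out), dtype=dtype)
        cview = cols.reshape(c_in, k, b_sz, l_out)
        for kk in range(k):
            cview[:, kk] = xp[:, :, kk : kk + l_out]
    w2 = weight.data.reshape(c_out, c_in * k)
    y = (w2 @ cols).reshape(c_out, b_sz, l_out)
    out_data = np.ascontiguousarray(y.transpose(1, 0, 2))
    out_data += bias.data[:, None]
    req = x.requires_grad or weight.requires_grad or bias.requires_grad

    def backward(g: np.ndarray) -> None:
        gt = np.ascontiguousarray(g.transpose(1, 0, 2))  # (C_out, B, L_out)
        g2 = gt.reshape(c_out, b_sz * l_out)
        if bias.requires_grad:
            bias._accumulate(gt.sum(axis=(1, 2)))
        if weight.requires_grad:
            weight._accumulate((g2 @ cols.T).reshape(c_out, c_in, k))
        if x.requires_grad:
            gcols = (w2.T @ g2).reshape(c_in, k, b_sz, l_out)
            if k == 1:
                gx = gcols[:, 0]
            else:
                gxp = np.zeros_like(xp)
                for kk in range(k):
                    gxp[:, :, kk : kk + l_out] += gcols[:, kk]
                gx = gxp[:, :, padding : padding + length]
            x._accumulate(np.ascontiguousarray(gx.transpose(1, 0, 2)))

    return Tensor(out_data, req, (x, weight, bias), backward)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, scale: float) -> Tensor:
    """Fused softmax(Q K^T * scale) V for (B, H, L, d_k) head tensors.

    Equivalent to ``matmul(softmax(matmul(q, k^T) * scale), v)`` but
    processed in batch chunks so the score matrix passes (forward and
    backward) stay cache-resident; only the softmax output is materialised
    in full (the backward pass needs it).  Returns a tensor whose
    ``data`` is the head outputs; the attention maps are exposed on the
    returned tensor's ``attention_maps`` attribute via the closure owner.
    """
    qd, kd, vd = q.data, k.data, v.data
    b, h, lq, dk = qd.shape
    lk = kd.shape[2]
    dtype = qd.dtype
    scale = np.asarray(scale, dtype=dtype)[()]
    # fold the scale into Q (a d_k-wide array) instead of spending a full
    # pass over the L x L score matrix
    qd = qd * scale
    # chunk the batch so one score block is ~32 MB (cache-friendly without
    # drowning in per-chunk dispatch overhead)
    chunk = max(1, int(32e6 / max(1, h * lq * lk * dtype.itemsize)))
    s = np.empty((b, h, lq, lk), dtype=dtype)
    out = np.empty((b, h, lq, dk), dtype=dtype)
    kt = np.ascontiguousarray(np.swapaxes(kd, -1, -2))
    for lo in range(0, b, chunk):
        hi = min(lo + chunk, b)
        blk = s[lo:hi]
        np.matmul(qd[lo:hi], kt[lo:hi], out=blk)
        mx = blk.max(axis=-1, keepdims=True)
        np.subtract(blk, mx, out=blk)
        np.exp(blk, out=blk)
        blk /= blk.sum(axis=-1, keepdims=True)
        np.matmul(blk, vd[lo:hi], out=out[lo:hi])
    req = q.requires_grad or k.requires_grad or v.requires_grad

    def backward(g: np.ndarray) -> None:
        gq = np.empty_like(qd) if q.requires_grad else None
        gk = np.empty_like(kd) if k.requires_grad else None
        gv = np.empty_like(vd) if v.requires_grad else None
        for lo in range(0, b, chunk):
            hi = min(lo + chunk, b)
            gc = g[lo:hi]
            sc = s[lo:hi]
            if gv is not None:
                np.matmul(np.swapaxes(sc, -1, -2), gc, out=gv[lo:hi])
            # score gradient, computed in place on its own scratch block
            da = gc @ np.swapaxes(vd[lo:hi], -1, -2)
            ds2 = da.reshape(-1, lk)
            _kernels.softmax_bwd_inplace(ds2, sc.reshape(-1, lk))
            if gq is not None:
                np.matmul(da, kd[lo:hi], out=gq[lo:hi])
            if gk is not None:
                # qd already carries the scale, as gq must
                np.matmul(np.swapaxes(da, -1, -2), qd[lo:hi], out=gk[lo:hi])
        if gq is not None:
            gq *= scale
            q._accumulate(gq)
        if gk is not None:
            k._accumulate(gk)
        if gv is not None:
            v._accumulate(gv)

    result = Tensor(out, req, (q, k, v), backward)
    result.attention_maps = s
    return result
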