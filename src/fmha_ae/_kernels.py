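"""Fused numerical kernels for the hot inner loops.

Row-wise softmax and layer-normalisation (forward and backward) account
for a large share of training time when written as chains of numpy
elementwise calls, because every link makes a full pass over attention-map
sized arrays.  The fused single-pass versions here are JIT-compiled with
numba when it is available; otherwise the numpy fallbacks keep the package
fully functional (identical results, just slower).

All kernels take 2-D contiguous views: callers reshape (..., N) to
(rows, N).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every model test
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=True)
def _softmax_fwd_jit(x):
    out = np.empty_like(x)
    rows, n = x.shape
    for r in range(rows):
        mx = x[r, 0]
        for j in range(1, n):
            if x[r, j] > mx:
                mx = x[r, j]
        total = 0.0
        for j in range(n):
            v = np.exp(x[r, j] - mx)
            out[r, j] = v
            total += v
        inv = 1.0 / total
        for j in range(n):
            out[r, j] *= inv
    return out


@njit(cache=True, fastmath=True)
def _softmax_bwd_jit(g, s):
    out = np.empty_like(g)
    rows, n = g.shape
    for r in range(rows):
        dot = 0.0
        for j in range(n):
            dot += g[r, j] * s[r, j]
        for j in range(n):
            out[r, j] = s[r, j] * (g[r, j] - dot)
    return out


@njit(cache=True, fastmath=True)
def _softmax_bwd_inplace_jit(g, s):
    """Overwrite ``g`` with the softmax Jacobian-vector product."""
    rows, n = g.shape
    for r in range(rows):
        dot = 0.0
        for j in range(n):
            dot += g[r, j] * s[r, j]
        for j in range(n):
            g[r, j] = s[r, j] * (g[r, j] - dot)


@njit(cache=True, fastmath=True)
def _layernorm_fwd_jit(x, w, b, eps):
    rows, n = x.shape
    out = np.empty_like(x)
    xhat = np.empty_like(x)
    invs = np.empty(rows, dtype=x.dtype)
    for r in range(rows):
        mu = 0.0
        for j in range(n):
            mu += x[r, j]
        mu /= n
        var = 0.0
        for j in range(n):
            d = x[r, j] - mu
            var += d * d
        var /= n
        inv = 1.0 / np.sqrt(var + eps)
        invs[r] = inv
        for j in range(n):
            h = (x[r, j] - mu) * inv
            xhat[r, j] = h
            out[r, j] = h * w[j] + b[j]
    return out, xhat, invs


@njit(cache=True, fastmath=True)
def _layernorm_bwd_jit(g, xhat, invs, w):
    rows, n = g.shape
    gx = np.empty_like(g)
    gw = np.zeros(n, dtype=g.dtype)
    gb = np.zeros(n, dtype=g.dtype)
    for r in range(rows):
        m1 = 0.0
        m2 = 0.0
        for j in range(n):
            gw[j] += g[r, j] * xhat[r, j]
            gb[j] += g[r, j]
            gwj = g[r, j] * w[j]
            m1 += gwj
            m2 += gwj * xhat[r, j]
        m1 /= n
        m2 /= n
        for j in range(n):
            gx[r, j] = invs[r] * (g[r, j] * w[j] - m1 - xhat[r, j] * m2)
    return gx, gw, gb


# -- numpy fallbacks ---------------------------------------------------------


def _softmax_fwd_np(x):
    s = x - x.max(axis=-1, keepdims=True)
    np.exp(s, out=s)
    s /= s.sum(axis=-1, keepdims=True)
    return s


def _softmax_bwd_np(g, s):
    dot = np.einsum("ij,ij->i", g, s)
    out = g - dot[:, None]
    out *= s
    return out


def _softmax_bwd_inplace_np(g, s):
    dot = np.einsum("ij,ij->i", g, s)
    g -= dot[:, None]
    g *= s


def _layernorm_fwd_np(x, w, b, eps):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return xhat * w + b, xhat, inv[:, 0]


def _layernorm_bwd_np(g, xhat, invs, w):
    gw = np.einsum("ij,ij->j", g, xhat)
    gb = g.sum(axis=0)
    gx_w = g * w
    m1 = gx_w.mean(axis=-1, keepdims=True)
    m2 = (gx_w * xhat).mean(axis=-1, keepdims=True)
    gx = invs[:, None] * (gx_w - m1 - xhat * m2)
    return gx, gw, gb


if _HAVE_NUMBA:
    # numpy's vectorised exp beats a scalar JIT loop for the forward pass;
    # the backward reduction fuses well and wins under JIT
    softmax_fwd = _softmax_fwd_np
    softmax_bwd = _softmax_bwd_jit
    softmax_bwd_inplace = _softmax_bwd_inplace_jit
    layernorm_fwd = _layernorm_fwd_jit
    layernorm_bwd = _layernorm_bwd_jit
else:  # pragma: no cover
    softmax_fwd = _softmax_fwd_np
    softmax_bwd = _softmax_bwd_np
    softmax_bwd_inplace = _softmax_bwd_inplace_np
    layernorm_fwd = _layernorm_fwd_np
    layernorm_bwd = _layernorm_bwd_np
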