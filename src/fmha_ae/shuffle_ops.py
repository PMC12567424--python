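"""1D feature shuffle / unshuffle rearrangement operators.

These are the one-dimensional analogue of pixel (un)shuffle, applied to a
``CH x N`` feature map (channels x samples).  ``feature_unshuffle``
de-interleaves each channel's even- and odd-indexed samples into two
channels, halving the length; ``feature_shuffle`` is its exact inverse,
interleaving consecutive channel pairs back into a single channel of twice
the length.  Both are lossless permutations of the elements: together with a
point-wise convolution they realise down-/up-sampling without pooling,
striding, or transposed convolution.

The rearrangement factor is fixed at 2: the encoder only ever halves the
length and the decoder only ever doubles it, and fixing the factor keeps the
index maps exactly the two-case even/odd formulas they implement.
"""

from __future__ import annotations

import numpy as np

__all__ = ["feature_unshuffle", "feature_shuffle"]


def _as_feature_map(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError(f"feature map must be 2-D (CH x N), got shape {x.shape}")
    if x.shape[0] < 1 or x.shape[1] < 1:
        raise ValueError(f"feature map must be non-empty, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    return x


def feature_unshuffle(x: np.ndarray) -> np.ndarray:
    """De-interleave a ``CH x N`` map into ``2*CH x N/2``.

    Channel ``2k`` of the output receives the even-indexed samples of input
    channel ``k`` and channel ``2k+1`` the odd-indexed samples::

        out[2k, j] = x[k, 2j]
        out[2k + 1, j] = x[k, 2j + 1]

    Parameters
    ----------
    x : ndarray of shape (CH, N)
        Input feature map; ``N`` must be even.

    Returns
    -------
    ndarray of shape (2*CH, N // 2)
        A fresh array (never a view of ``x``).
    """
    x = _as_feature_map(x)
    ch, n = x.shape
    if n % 2 != 0:
        raise ValueError(f"feature_unshuffle requires an even length, got N={n}")
    # (CH, N) -> (CH, N/2, 2) -> (CH, 2, N/2) -> (2*CH, N/2)
    return np.ascontiguousarray(
        x.reshape(ch, n // 2, 2).transpose(0, 2, 1).reshape(2 * ch, n // 2)
    )


def feature_shuffle(x: np.ndarray) -> np.ndarray:
    """Interleave a ``2*CH x N/2`` map back into ``CH x N``.

    Exact inverse of :func:`feature_unshuffle`::

        out[k, i] = x[2k, i // 2]        if i is even
        out[k, i] = x[2k + 1, (i-1)//2]  if i is odd

    Parameters
    ----------
    x : ndarray of shape (2*CH, N // 2)
        Input feature map; the channel count must be even.

    Returns
    -------
    ndarray of shape (CH, N)
        A fresh array (never a view of ``x``).
    """
    x = _as_feature_map(x)
    ch2, half = x.shape
    if ch2 % 2 != 0:
        raise ValueError(
            f"feature_shuffle requires an even channel count, got CH={ch2}"
        )
    # (2*CH, N/2) -> (CH, 2, N/2) -> (CH, N/2, 2) -> (CH, N)
    return np.ascontiguousarray(
        x.reshape(ch2 // 2, 2, half).transpose(0, 2, 1).reshape(ch2 // 2, 2 * half)
    )
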