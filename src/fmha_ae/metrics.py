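"""Denoising quality metrics for aligned clean / noisy / denoised signals.

Conventions:

* ``snr_in_ratio`` / ``snr_out_ratio`` are *pure power ratios*
  (sum of squares of the clean signal over sum of squared error); the
  decibel conversion happens only in ``snr_improvement_db``.
* PRD is the root of the error-to-signal energy ratio times 100, so a
  reconstruction of all zeros scores exactly 100 %.
* A denoiser that returns the noisy input unchanged scores an SNR
  improvement of exactly 0 dB; negative values mean the "denoiser" made
  the signal worse.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "snr_in_ratio",
    "snr_out_ratio",
    "snr_improvement_db",
    "prd_percent",
    "rmse",
    "mse_loss",
]


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 1:
        raise ValueError("signals must be non-empty")
    return x, y


def _snr_ratio(clean: np.ndarray, other: np.ndarray) -> float:
    signal_power = float(np.sum(clean**2))
    error_power = float(np.sum((clean - other) ** 2))
    if signal_power <= 0.0:
        raise ValueError("clean signal has zero energy; SNR undefined")
    if error_power == 0.0:
        return math.inf  # perfect reconstruction sentinel
    return signal_power / error_power


def snr_in_ratio(clean, noisy) -> float:
    """Input SNR as a power ratio: sum(x^2) / sum((x - x~)^2)."""
    return _snr_ratio(*_pair(clean, noisy))


def snr_out_ratio(clean, denoised) -> float:
    """Output SNR as a power ratio: sum(x^2) / sum((x - x^)^2)."""
    return _snr_ratio(*_pair(clean, denoised))


def snr_improvement_db(clean, noisy, denoised) -> float:
    """10 log10(SNR_out) - 10 log10(SNR_in), in decibels."""
    snr_in = snr_in_ratio(clean, noisy)
    snr_out = snr_out_ratio(clean, denoised)
    if math.isinf(snr_out):
        return math.inf
    return 10.0 * math.log10(snr_out) - 10.0 * math.log10(snr_in)


def prd_percent(clean, denoised) -> float:
    """Percentage root-mean-square difference, in percent."""
    clean, denoised = _pair(clean, denoised)
    signal_power = float(np.sum(clean**2))
    if signal_power <= 0.0:
        raise ValueError("clean signal has zero energy; PRD undefined")
    return 100.0 * math.sqrt(float(np.sum((clean - denoised) ** 2)) / signal_power)


def rmse(clean, denoised) -> float:
    """Root-mean-square error between clean and denoised signals."""
    clean, denoised = _pair(clean, denoised)
    return math.sqrt(float(np.mean((clean - denoised) ** 2)))


def mse_loss(targets, outputs) -> float:
    """Mean squared error over all elements of two equal-shape batches."""
    targets = np.asarray(targets, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if targets.shape != outputs.shape:
        raise ValueError(
            f"shape mismatch: targets {targets.shape} vs outputs {outputs.shape}"
        )
    return float(np.mean((targets - outputs) ** 2))
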