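"""Synthetic single-lead ECG and the four canonical artifact classes.

The clean signal is a quasi-periodic sum-of-Gaussians PQRST train sampled
at 360 Hz: each beat is the superposition of five Gaussian bumps whose
amplitudes (mV), centre offsets (s) and widths (s) approximate the normal
adult morphology.  RR intervals jitter multiplicatively around the chosen
heart rate.  The sum-of-Gaussians form was chosen over a dynamical-system
model because it admits exact analytic oracles (beat counts, peak
positions) for testing.

Artifact classes:

* electrode motion (EM): low-pass-filtered Gaussian noise (< 10 Hz) plus
  sparse Poisson-arriving smoothed baseline steps of R-wave-scale
  amplitude - the large transients that can mimic ectopic beats;
* baseline wander (BW): a mixture of random-phase sinusoids below 0.5 Hz;
* muscle artifact (MA): Gaussian noise band-passed to 20-150 Hz;
* power-line interference (PLI): a 60 Hz sinusoid with random phase.

Every generator derives its own stream from the master seed (one stream
per artifact class), so adding one noise type never perturbs another's
draws.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal as sps

from .data_prep import NOISE_LEVELS_DB, SegmentPair, make_pair

__all__ = [
    "SynthConfig",
    "DEFAULT_WAVES",
    "synth_ecg",
    "synth_em_noise",
    "synth_bw",
    "synth_ma",
    "synth_pli",
    "generate_dataset",
]

# per-wave (amplitude mV, centre offset s relative to the R peak, width s)
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (0.10, -0.20, 0.040),
    "Q": (-0.15, -0.05, 0.010),
    "R": (1.00, 0.00, 0.015),
    "S": (-0.25, 0.05, 0.010),
    "T": (0.30, 0.30, 0.070),
}

# salts separating the per-class random streams spawned from the master seed
_STREAM_ECG, _STREAM_EM, _STREAM_BW, _STREAM_MA, _STREAM_PLI = range(5)


@dataclasses.dataclass
class SynthConfig:
    """Parameters of the synthetic generators.

    ``heart_rate=None`` draws a rate uniformly from 60-100 bpm (seeded).
    Amplitudes are in the clean signal's mV scale; they only matter
    relative to each other because mixing rescales noise to a target SNR.
    """

    sampling_rate: float = 360.0
    duration: float = 10.0
    heart_rate: Optional[float] = None
    rr_jitter: float = 0.05
    waves: dict[str, tuple[float, float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_WAVES)
    )
    em_noise_std: float = 1.0
    em_step_rate: float = 0.3  # baseline steps per second
    em_step_amp: float = 1.0  # step amplitude scale (R-wave order)
    bw_amplitude: float = 1.0
    bw_components: int = 5
    ma_std: float = 1.0
    pli_amplitude: float = 1.0
    pli_freq: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        for name, (_, _, width) in self.waves.items():
            if width <= 0:
                raise ValueError(f"wave {name} must have positive width")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, stream])


def synth_ecg(config: SynthConfig) -> np.ndarray:
    """Quasi-periodic PQRST train; deterministic given the seed.

    Beat centres start at half an RR interval and advance by jittered RR
    intervals, so a duration of ``n`` base intervals contains exactly ``n``
    beats when the jitter is zero.
    """
    rng = config._rng(_STREAM_ECG)
    hr = (
        config.heart_rate
        if config.heart_rate is not None
        else rng.uniform(60.0, 100.0)
    )
    rr = 60.0 / hr
    if config.duration < rr:
        raise ValueError(
            f"duration {config.duration} s holds no complete beat at {hr} bpm"
        )
    centers = []
    t_beat = 0.5 * rr * (1.0 + config.rr_jitter * rng.standard_normal())
    margin = max(abs(off) + 5 * w for _, off, w in config.waves.values())
    while t_beat < config.duration + margin:
        centers.append(t_beat)
        step = rr * (1.0 + config.rr_jitter * rng.standard_normal())
        t_beat += max(step, 0.2 * rr)  # keep intervals positive
    t = np.arange(config.n_samples) / config.sampling_rate
    ecg = np.zeros_like(t)
    for c in centers:
        for amp, off, width in config.waves.values():
            if amp == 0.0:
                continue
            ecg += amp * np.exp(-((t - c - off) ** 2) / (2.0 * width**2))
    return ecg


def synth_em_noise(config: SynthConfig) -> np.ndarray:
    """Electrode-motion artifact: < 10 Hz coloured noise + baseline steps."""
    rng = config._rng(_STREAM_EM)
    n, fs = config.n_samples, config.sampling_rate
    out = np.zeros(n)
    if config.em_noise_std > 0:
        white = rng.standard_normal(n) * config.em_noise_std
        sos = sps.butter(4, 10.0, btype="lowpass", fs=fs, output="sos")
        out += sps.sosfiltfilt(sos, white)
    if config.em_step_rate > 0 and config.em_step_amp > 0:
        n_steps = rng.poisson(config.em_step_rate * config.duration)
        if n_steps > 0:
            positions = rng.integers(0, n, size=n_steps)
            amps = rng.standard_normal(n_steps) * config.em_step_amp
            steps = np.zeros(n)
            for pos, amp in zip(positions, amps):
                steps[pos:] += amp
            # smooth the edges over ~50 ms so steps look like electrode slips
            out += ndimage.gaussian_filter1d(steps, sigma=0.05 * fs)
    return out


def synth_bw(config: SynthConfig) -> np.ndarray:
    """Baseline wander: random-phase sinusoids below 0.5 Hz."""
    rng = config._rng(_STREAM_BW)
    t = np.arange(config.n_samples) / config.sampling_rate
    out = np.zeros_like(t)
    if config.bw_amplitude == 0.0:
        return out
    freqs = rng.uniform(0.05, 0.45, size=config.bw_components)
    amps = rng.uniform(0.5, 1.0, size=config.bw_components)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=config.bw_components)
    for f, a, p in zip(freqs, amps, phases):
        out += a * np.sin(2.0 * math.pi * f * t + p)
    return config.bw_amplitude * out


def synth_ma(config: SynthConfig) -> np.ndarray:
    """Muscle artifact: Gaussian noise band-passed to 20-150 Hz."""
    rng = config._rng(_STREAM_MA)
    n, fs = config.n_samples, config.sampling_rate
    if config.ma_std == 0.0:
        return np.zeros(n)
    high = min(150.0, 0.95 * fs / 2.0)  # truncate at Nyquist
    sos = sps.butter(4, [20.0, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, rng.standard_normal(n) * config.ma_std)


def synth_pli(config: SynthConfig) -> np.ndarray:
    """Power-line interference: mains-frequency sinusoid, random phase."""
    rng = config._rng(_STREAM_PLI)
    t = np.arange(config.n_samples) / config.sampling_rate
    phase = rng.uniform(0.0, 2.0 * math.pi)
    return config.pli_amplitude * np.sin(
        2.0 * math.pi * config.pli_freq * t + phase
    )


def generate_dataset(
    n_segments: int,
    snr_levels: Sequence[float] = NOISE_LEVELS_DB,
    seed: int = 0,
    segment_length: int = 1024,
    sampling_rate: float = 360.0,
) -> list[SegmentPair]:
    """Build a dataset of preprocessed (noisy, clean) EM-noise pairs.

    Each segment draws its own heart rate and noise realisation from a
    stream spawned off the master seed; nominal SNR levels are assigned
    round-robin so the dataset is balanced across levels.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if not snr_levels:
        raise ValueError("snr_levels must be non-empty")
    children = np.random.SeedSequence(seed).spawn(n_segments)
    duration = segment_length / sampling_rate
    pairs = []
    for i in range(n_segments):
        child_seed = int(children[i].generate_state(1)[0] & 0x7FFFFFFF)
        cfg = SynthConfig(
            sampling_rate=sampling_rate,
            duration=duration,
            seed=child_seed,
        )
        clean = synth_ecg(cfg)[:segment_length]
        noise = synth_em_noise(cfg)[:segment_length]
        level = float(snr_levels[i % len(snr_levels)])
        pairs.append(
            make_pair(clean, noise, level, source_id=f"synthetic-ecg-{i}")
        )
    return pairs
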