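# Methods

## Problem

Single-lead ambulatory ECG is routinely corrupted by electrode-motion (EM)
artifact: large, non-stationary transients from shifts of the
electrode-skin interface.  Unlike baseline wander or mains pickup, EM
noise overlaps the spectral band of the cardiac waves themselves and can
mimic ectopic beats, so fixed-band filtering cannot separate it from
signal.  This package implements a learned denoiser — a feature-shuffle
multi-head attention autoencoder (FMHA-AE) — together with the classical
FIR/IIR/wavelet comparison filters, the evaluation metrics, the
preprocessing protocol, and a synthetic data generator that makes the
whole pipeline exercisable without downloading clinical databases.

## Model

The network maps a noisy 1 x 1024 segment (360 Hz, about 2-4 beats) to a
denoised segment of the same size.

* **Input layer**: a 1x1 convolution expands 1 -> C channels (C = 128 by
  default), followed by a residual block `y = ReLU(conv(ReLU(conv(x))) + x)`
  with kernel 5 and padding 2.
* **Encoder** (7 stages): each stage runs a residual block, then a
  *feature unshuffle* — the 1-D analogue of pixel unshuffle, which
  de-interleaves even/odd samples into separate channels (C -> 2C,
  L -> L/2) — then a point-wise convolution back to C channels, then
  multi-head self-attention over the L/2 time steps
  (`head_i = softmax(Q_i K_i^T / sqrt(d_k)) V_i`, d_k = C/h, h = 4),
  and a position-wise feed-forward network (C -> 4C -> C, ReLU).  The
  attention and FFN sub-blocks carry residual connections with post-layer
  normalisation over the channel axis.  Seven stages shrink 1024 -> 8.
* **Shortcuts** (6): each intermediate encoder resolution feeds a
  shape-preserving block whose attention operates *between channels*
  (`A_i = softmax(Q_i^T K_i / sqrt(L))`, a d_k x d_k map applied as
  `V_i A_i`), followed by the same FFN/normalisation structure.  Its
  parameters all live on the channel axis, so the count is independent of
  sequence length.  The shortcut output is added element-wise to the
  decoder path at the matching resolution.
* **Decoder** (7 stages): residual block, point-wise convolution C -> 2C,
  *feature shuffle* (the exact inverse interleave, 2C -> C, L -> 2L), then
  multi-head cross-attention whose queries come from the decoder path and
  whose keys/values come from the final encoder output (the 128 x 8
  bottleneck), then the FFN.  Every decoder stage attends to the same raw
  bottleneck.  The stage that consumes the bottleneck itself receives no
  shortcut, matching the six-shortcut layout.
* **Output layer**: one residual block, then a 1x1 convolution C -> 1.

There is no positional encoding; the interleave structure and
convolutions carry the ordering information.  All convolutions and
projections have biases.  At the default geometry the per-block trainable
parameter counts are: input layer 164,352; encoder block 395,264;
shortcut block 198,272; decoder block 395,392; output layer 164,225
(7,052,801 in total) — the package treats this accounting as normative
and asserts it in the acceptance suite.

### Design choices where the composition was open

* Normalisation placement is post-norm (after each residual join), the
  original transformer convention.
* Residual connections around attention/FFN are parameter-free, and the
  shortcut merge is element-wise addition — any learned merge would
  change the per-block counts above.
* The channel-attention scale is `1/sqrt(L)` (the size of the contracted
  token axis), mirroring `1/sqrt(d_k)` in time-step attention.
* Weight initialisation is fan-in uniform (`U(+-1/sqrt(fan_in))`) for all
  convolutions and projections, ones/zeros for normalisation, fully
  determined by `ModelConfig.seed`.
* The rearrangement factor of the shuffle operators is fixed at 2; the
  architecture only ever halves or doubles the length.

## Numerical implementation

The network, reverse-mode automatic differentiation, and Adam training
loop are implemented directly over numpy, with the hot paths engineered
for single-CPU throughput: attention is a fused, batch-chunked op whose
softmax passes run on cache-resident blocks; convolutions are one im2col
GEMM per layer in a channel-major layout; softmax/layer-norm backward
reductions are JIT-compiled with numba when available (bit-identical
numpy fallbacks otherwise); gradient buffers are adopted without copies
where single-contribution, and the glibc mmap threshold is raised so
large activation buffers are reused.  Every primitive's backward pass is
verified against central finite differences in the test suite, and the
attention/FFN forward paths against brute-force loop oracles at 1e-10.

Float32 is used for training-scale runs and float64 for oracle tests
(`ModelConfig.dtype`).  Checkpoints are `.npz` archives containing a JSON
header (format version + full config) plus every named parameter.

## Data protocol

Signals are cut into non-overlapping 1024-sample segments (trailing
remainder discarded), DC-removed, and scaled symmetrically so
`max(|x|) = 1` — symmetric max-abs scaling preserves the zero mean, which
min-max scaling would not.  Noise is then mixed at an exact nominal input
SNR: the noise segment is scaled so that
`10 log10(sum(x^2)/sum((a n)^2))` equals the target level, using the
segment's own energies.  Because additive mixing at -6 dB pushes the
noisy trace outside [-1, 1], the clean and noisy signals are rescaled
jointly by `1/max(1, max|noisy|)`; SNR is scale-invariant, so the nominal
level is preserved to better than 1e-6 dB while both traces stay bounded.
Datasets are split 80:20 (`ceil(0.8 n)` train), deterministically per
seed.  The six nominal levels are -6, 0, 6, 12, 18, 24 dB.

A minimal read-only WFDB loader (header + formats 212/16) supports the
optional real-data path (MITDB/NSTDB records); those records ship
pre-mixed, so mixing is skipped and the record's nominal level is
trusted.

## Synthetic data

The clean signal is a quasi-periodic sum-of-Gaussians PQRST train at
360 Hz: per beat, five Gaussian bumps with default (amplitude mV,
offset s, width s) P(0.10, -0.20, 0.040), Q(-0.15, -0.05, 0.010),
R(1.00, 0, 0.015), S(-0.25, 0.05, 0.010), T(0.30, 0.30, 0.070); the heart
rate is drawn uniformly from 60-100 bpm per segment and RR intervals
jitter multiplicatively (sd 5 %).  This morphology was chosen over a
dynamical-system model because it admits exact analytic oracles (beat
counts, peak positions).  Artifacts: EM = sub-10 Hz low-passed Gaussian
noise plus Poisson-arriving smoothed baseline steps of R-wave-scale
amplitude (0.3 events/s); BW = random-phase sinusoids below 0.5 Hz;
MA = 20-150 Hz band-passed Gaussian noise; PLI = a 60 Hz sinusoid with
random phase.  Each class draws from its own stream spawned off the
master seed, so adding one noise type never perturbs another's draws.

What the synthetic data does *not* emulate: arrhythmic morphologies,
inter-lead correlation, heteroscedastic sensor gain, or the NSTDB's
alternating clean/noisy 2-minute layout.  Passing the synthetic suite
therefore demonstrates that the architecture, optimisation and metrics
behave as specified — not clinical-grade performance on real records.

## Training and evaluation

The full-scale recipe is MSE loss, Adam, batch 32, learning rate 1e-4
halving every 200 epochs (`floor(epoch/200)`), 1000 epochs
(`configs/default.yaml`); no early stopping, clipping or weight decay.
Evaluation reports per-level and average SNR improvement
(`10 log10(SNR_out) - 10 log10(SNR_in)`, both pure power ratios), PRD
(`100 sqrt(sum(x - x_hat)^2 / sum x^2)` — the radical is included so an
all-zero reconstruction scores exactly 100 %), and RMSE, computed per
segment and averaged uniformly within each level; the report's average
row is the unweighted mean over levels.

### Desk-scale benchmark

`desk_benchmark()` trains a width-32 / depth-4 model on 2000 synthetic EM
pairs for 20 epochs (batch 32, MSE, Adam) and evaluates on the held-out
20 %.  Its learning rate is 1e-3 rather than the full recipe's 1e-4: with
a 20-epoch budget instead of 1000, the full-scale rate cannot move the
model meaningfully off its initialisation.  The automated test suite runs
a reduced instance of the same study — 1000 pairs, 8 epochs — a problem
size chosen so the whole suite remains comfortably runnable on one CPU;
at that scale the model reaches about +5 dB SNR improvement at 0 dB input
(the assertion bar is +3 dB), with the training loss falling and the
trajectory exactly reproducible from the seed.

## Classical baselines

All three denoisers realise a 0.67-40 Hz band at 360 Hz:

* **FIR**: 101 taps, Hanning window.  The band-pass is constructed as the
  difference of two unit-DC-gain window-method low-passes (high-pass via
  spectral inversion): with 101 taps the transition band (~22 Hz) dwarfs
  the 0.67 Hz edge, and this construction is what pins the DC gain to
  exactly zero so sub-band drift is actually rejected.  Applied with
  group-delay compensation (centred convolution; odd tap count gives an
  integer delay).
* **IIR**: fourth-order Butterworth band-pass, applied forward-backward
  (zero phase) to avoid distorting the QRS complex; section pole radii
  are checked before filtering.
* **DWT**: db6, nine levels, symmetric extension; the d1 and d2 detail
  bands (~45-180 Hz) and the level-9 approximation (below ~0.35 Hz) are
  zeroed before reconstruction.  Signals shorter than 2^9 samples are
  decomposed at the maximal usable level with a warning.

All three are linear and length-preserving, verified to 1e-8.

## Known limitations

* The desk-scale study is a qualitative demonstration; reproducing the
  published full-scale figures requires the real MITDB/NSTDB records and
  the 1000-epoch recipe (`scripts/full_reproduction.py`), which is far
  outside a test-suite budget.
* The per-block parameter accounting is asserted for the documented
  composition; alternative readings of the prose architecture (e.g. a
  learned shortcut merge) are intentionally not supported.
* Multiply-accumulate (MACs) accounting is not implemented; counting
  conventions vary too much to pin a single number.
* The WFDB reader handles single-file records in formats 212/16 only, and
  reads no annotations.
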