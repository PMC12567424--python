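# fmha-ae — attention-based removal of electrode-motion noise from ECG

Electrode-motion (EM) artifact is the hardest common contaminant of
ambulatory single-lead ECG: large transients from electrode-skin shifts
that overlap the cardiac band and can mimic ectopic beats, defeating
fixed-band filters.  This package implements the **feature-shuffle
multi-head attention autoencoder (FMHA-AE)** — a 1-D encoder/decoder that
downsamples by de-interleaving samples into channels (the 1-D analogue of
pixel unshuffle) and applies multi-head self-attention over time steps in
the encoder, channel-correlation attention in the shortcut path, and
cross-attention against the bottleneck in the decoder:

    head_i = softmax(Q_i K_i^T / sqrt(d_k)) V_i,   d_k = C / h

with C = 128 channels, h = 4 heads, seven encoder stages
(1 x 1024 -> 128 x 8) and seven decoder stages back to 1 x 1024.  The
package also ships the classical FIR / IIR / wavelet comparison
denoisers, the SNR-controlled noise-mixing and preprocessing protocol,
the evaluation metrics (SNR improvement, PRD, RMSE), and a synthetic
ECG + artifact generator so everything runs without downloading clinical
databases.  It is aimed at biomedical-signal-processing researchers who
want a transparent, dependency-light (numpy/scipy) reference
implementation — the network, autodiff and Adam loop are all in the
package, with every gradient checked against finite differences.

## Worked example

Train the desk-scale model on synthetic electrode-motion noise and
evaluate per noise level (about five minutes on one CPU):

```python
from fmha_ae import desk_benchmark

run = desk_benchmark(seed=1, n_pairs=1000, epochs=8)
print(run["report"].per_level)
```

```
 noise_level_db  snr_imp_db  prd_percent     rmse
           -6.0    7.607656    87.698979 0.116383
            0.0    5.076636    57.734637 0.104551
            6.0    2.930260    36.690544 0.074361
           12.0    0.316984    24.487528 0.051379
           18.0   -2.853201    17.629583 0.038572
           24.0   -7.822798    15.657521 0.034911
```

Each row is the held-out test set at one nominal input SNR.
`snr_imp_db` is the decibel gain of output SNR over input SNR (positive =
successful denoising): at 0 dB input — noise as strong as the signal —
the small model already recovers +5 dB after eight epochs.  `prd_percent`
is the percentage root-mean-square difference to the clean signal (an
all-zero output would score 100 %), and `rmse` its unnormalised
counterpart.  The trend — large gains under heavy noise, diminishing and
eventually negative gains where the input is already clean — mirrors what
both the learned and classical methods show at full scale.

The same things are scriptable from the shell:

```sh
fmha-ae simulate --n-segments 600 --seed 0 --out data.csv
fmha-ae train    --data data.csv --width 32 --depth 4 --epochs 8 --seed 0
fmha-ae evaluate --data data.csv --checkpoint runs/model.npz --out report.csv
fmha-ae denoise  --method dwt --input signal.txt --out denoised.txt
fmha-ae count-params --width 128 --depth 7
```

`count-params` prints the architecture table; at the default geometry the
distinct block counts are input layer 164,352, encoder block 395,264,
shortcut block 198,272, decoder block 395,392, output layer 164,225
(7,052,801 total trainable parameters).

Full-scale training on the real MIT-BIH records (MITDB clean references,
NSTDB electrode-motion variants at -6...24 dB) is supported through
`scripts/full_reproduction.py`; it needs the WFDB files from PhysioNet
and many hours of compute, and is deliberately outside the test suite.

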