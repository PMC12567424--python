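# Full-scale training configuration (the published recipe).
# Model geometry ------------------------------------------------------------
width: 128            # channels after input expansion; ablation: 64 / 128 / 256
depth: 7              # encoder = decoder stage count (1024 -> 8 bottleneck)
heads: 4              # attention heads; ablation: 2 / 4 / 8 / 16
d_ff: 512             # feed-forward hidden width (= 4 * width by default)
kernel: 5             # residual-block convolution length
segment_length: 1024  # samples per segment at 360 Hz (~2-4 beats)
dtype: float32
# Optimisation --------------------------------------------------------------
loss: mse
optimizer: adam
batch_size: 32
learning_rate: 1.0e-4   # halves every 200 epochs (step decay)
lr_decay_factor: 0.5
lr_decay_every: 200
epochs: 1000
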