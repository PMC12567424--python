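#!/usr/bin/env python
"""Full-scale study driver: real MITDB/NSTDB records, full training recipe.

This script is NOT part of the test suite.  It requires:

* the MIT-BIH Arrhythmia Database (MITDB) records 118 and 119 and the
  MIT-BIH Noise Stress Test Database (NSTDB) electrode-motion variants
  (118e_6, 118e00, 118e06, 118e12, 118e18, 118e24 and the 119 series),
  downloaded from PhysioNet into a local directory in WFDB format;
* hours of compute for the full 1000-epoch recipe at width 128 (the
  reference hardware was a desktop GPU; a CPU run takes far longer).

Usage:

    python scripts/full_reproduction.py --data-dir /path/to/records \\
        --out-dir runs/full --epochs 1000

Protocol: the clean MITDB signal is the target and the NSTDB
electrode-motion record at each nominal level is the input; both are cut
into non-overlapping 1024-sample segments, DC-removed and normalised to
[-1, 1]; segments are split 80:20; training uses MSE, Adam, batch 32 and a
step-LR schedule (1e-4 halving every 200 epochs).  NSTDB records are
pre-mixed by construction, so no SNR mixing is applied; each segment
carries its record's nominal level.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np

from fmha_ae.data_prep import (
    SegmentPair,
    preprocess_segment,
    segment_signal,
    split_dataset,
)
from fmha_ae.model import ModelConfig, build_model
from fmha_ae.pipeline import TrainConfig, evaluate, train
from fmha_ae.wfdb_io import read_wfdb_record

NSTDB_SUFFIXES = {
    "e_6": -6.0, "e00": 0.0, "e06": 6.0, "e12": 12.0, "e18": 18.0, "e24": 24.0,
}


def build_pairs(data_dir: Path, records=("118", "119")) -> list[SegmentPair]:
    pairs: list[SegmentPair] = []
    for record in records:
        clean = read_wfdb_record(data_dir / record)
        for suffix, level in NSTDB_SUFFIXES.items():
            noisy_path = data_dir / f"{record}{suffix}"
            if not noisy_path.with_suffix(".hea").exists():
                print(f"skipping missing record {noisy_path.name}")
                continue
            noisy = read_wfdb_record(noisy_path)
            for ch in range(clean.signals.shape[1]):
                clean_segs = segment_signal(clean.signals[:, ch])
                noisy_segs = segment_signal(noisy.signals[:, ch])
                for i, (c, n) in enumerate(zip(clean_segs, noisy_segs)):
                    try:
                        c_p = preprocess_segment(c)
                        n_p = preprocess_segment(n)
                    except ValueError:
                        continue  # flat segment
                    pairs.append(
                        SegmentPair(
                            noisy=n_p, clean=c_p, nominal_snr_db=level,
                            source_id=f"{record}{suffix}:{ch}:{i}",
                        )
                    )
    return pairs


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--out-dir", type=Path, default=Path("runs/full"))
    parser.add_argument("--epochs", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    pairs = build_pairs(args.data_dir)
    print(f"built {len(pairs)} segment pairs")
    train_pairs, test_pairs = split_dataset(pairs, seed=args.seed)

    model = build_model(ModelConfig(seed=args.seed, dtype="float32"))
    result = train(
        model, train_pairs,
        TrainConfig(epochs=args.epochs, seed=args.seed),
        test_pairs=test_pairs,
    )
    args.out_dir.mkdir(parents=True, exist_ok=True)
    result.model.save(args.out_dir / "model.npz")
    result.history.to_csv(args.out_dir / "history.csv", index=False)
    report = evaluate(result.model, test_pairs)
    report.to_csv(args.out_dir / "metrics.csv")
    print(report.per_level.to_string(index=False))


if __name__ == "__main__":
    main()
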