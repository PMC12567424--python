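"""Segment-level preprocessing: slicing, DC removal, normalisation,
SNR-controlled noise mixing, and train/test splitting.

The protocol operates on non-overlapping fixed-length segments (default
1024 samples at 360 Hz, i.e. 2-4 heartbeats).  Each clean segment has its
DC offset removed, is scaled symmetrically to [-1, 1], and is then mixed
with a noise segment at an exact nominal input SNR.  Because additive
mixing at low SNR can push the noisy trace outside [-1, 1], the clean and
noisy signals are rescaled *jointly* afterwards; SNR is scale-invariant, so
the nominal level is preserved exactly while both traces stay bounded.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SegmentPair",
    "segment_signal",
    "remove_dc",
    "normalize",
    "preprocess_segment",
    "mix_at_snr",
    "make_pair",
    "split_dataset",
    "save_pairs_csv",
    "load_pairs_csv",
    "save_pairs_npz",
    "load_pairs_npz",
    "stack_pairs",
]

NOISE_LEVELS_DB = (-6.0, 0.0, 6.0, 12.0, 18.0, 24.0)
SEGMENT_LENGTH = 1024


@dataclasses.dataclass
class SegmentPair:
    """One (noisy input, clean target) training example."""

    noisy: np.ndarray
    clean: np.ndarray
    nominal_snr_db: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.noisy = np.asarray(self.noisy, dtype=float)
        self.clean = np.asarray(self.clean, dtype=float)
        if self.noisy.shape != self.clean.shape or self.noisy.ndim != 1:
            raise ValueError("noisy and clean must be 1-D and equally long")
        if np.max(np.abs(self.noisy)) > 1.0 + 1e-9 or np.max(np.abs(self.clean)) > 1.0 + 1e-9:
            raise ValueError("segments must lie within [-1, 1] after preprocessing")


def segment_signal(signal, segment_length: int = SEGMENT_LENGTH) -> list[np.ndarray]:
    """Cut a 1-D signal into consecutive non-overlapping segments.

    The trailing remainder that does not fill a whole segment is discarded.
    A signal shorter than one segment yields an empty list with a warning.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    n_seg = signal.size // segment_length
    if n_seg == 0:
        warnings.warn(
            f"signal of length {signal.size} is shorter than one segment "
            f"({segment_length}); returning no segments",
            stacklevel=2,
        )
        return []
    trimmed = signal[: n_seg * segment_length]
    return list(trimmed.reshape(n_seg, segment_length))


def remove_dc(segment) -> np.ndarray:
    """Subtract the segment mean."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("cannot remove DC from an empty segment")
    return segment - segment.mean()


def normalize(segment) -> np.ndarray:
    """Scale symmetrically so that max(|segment|) == 1.

    Symmetric max-absolute scaling preserves the zero mean produced by
    :func:`remove_dc` (min-max scaling would not).
    """
    segment = np.asarray(segment, dtype=float)
    peak = np.max(np.abs(segment)) if segment.size else 0.0
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero segment")
    return segment / peak


def preprocess_segment(segment) -> np.ndarray:
    """DC removal followed by symmetric [-1, 1] normalisation."""
    return normalize(remove_dc(segment))


def mix_at_snr(clean, noise, target_snr_db: float) -> np.ndarray:
    """Add scaled noise so the realized input SNR equals the target exactly.

    The noise is multiplied by ``a = sqrt(P_clean / (P_noise * 10^(SNR/10)))``
    so that ``10 log10(sum(clean^2) / sum((a*noise)^2))`` is the requested
    level, measured with the segment's own energies.
    """
    clean = np.asarray(clean, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if clean.shape != noise.shape:
        raise ValueError("clean and noise must have the same shape")
    p_clean = float(np.sum(clean**2))
    p_noise = float(np.sum(noise**2))
    if p_clean <= 0.0:
        raise ValueError("clean signal is silent; SNR mixing undefined")
    if p_noise <= 0.0:
        raise ValueError("noise signal is silent; SNR mixing undefined")
    a = math.sqrt(p_clean / (p_noise * 10.0 ** (target_snr_db / 10.0)))
    return clean + a * noise


def make_pair(
    clean, noise, target_snr_db: float, source_id: str = ""
) -> SegmentPair:
    """Preprocess a clean segment, mix noise at the nominal SNR, and
    rescale the pair jointly into [-1, 1]."""
    clean = preprocess_segment(clean)
    noisy = mix_at_snr(clean, noise, target_snr_db)
    scale = max(1.0, float(np.max(np.abs(noisy))))
    return SegmentPair(
        noisy=noisy / scale,
        clean=clean / scale,
        nominal_snr_db=float(target_snr_db),
        source_id=source_id,
    )


def split_dataset(
    pairs: Sequence[SegmentPair],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[SegmentPair], list[SegmentPair]]:
    """Disjoint, exhaustive random split; train gets ceil(f * n) pairs."""
    n = len(pairs)
    if n < 5:
        raise ValueError(f"need at least 5 pairs to split, got {n}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = math.ceil(train_fraction * n)
    order = np.random.default_rng(seed).permutation(n)
    train = [pairs[i] for i in order[:n_train]]
    test = [pairs[i] for i in order[n_train:]]
    return train, test


# ---------------------------------------------------------------------------
# dataset import/export


def _pairs_frame(pairs: Sequence[SegmentPair]) -> pd.DataFrame:
    length = pairs[0].clean.size
    data = {
        "source_id": [p.source_id for p in pairs],
        "nominal_snr_db": [p.nominal_snr_db for p in pairs],
    }
    clean = np.stack([p.clean for p in pairs])
    noisy = np.stack([p.noisy for p in pairs])
    for j in range(length):
        data[f"clean_{j}"] = clean[:, j]
    for j in range(length):
        data[f"noisy_{j}"] = noisy[:, j]
    return pd.DataFrame(data)


def save_pairs_csv(pairs: Sequence[SegmentPair], path) -> None:
    """Columnar text export: source_id, nominal_snr_db, clean_*, noisy_*."""
    _pairs_frame(pairs).to_csv(path, index=False)


def load_pairs_csv(path) -> list[SegmentPair]:
    frame = pd.read_csv(path)
    clean_cols = [c for c in frame.columns if c.startswith("clean_")]
    noisy_cols = [c for c in frame.columns if c.startswith("noisy_")]
    return [
        SegmentPair(
            noisy=row[noisy_cols].to_numpy(dtype=float),
            clean=row[clean_cols].to_numpy(dtype=float),
            nominal_snr_db=float(row["nominal_snr_db"]),
            source_id=str(row["source_id"]),
        )
        for _, row in frame.iterrows()
    ]


def save_pairs_npz(pairs: Sequence[SegmentPair], path) -> None:
    """Compact binary container with the same fields as the CSV export."""
    np.savez_compressed(
        path,
        clean=np.stack([p.clean for p in pairs]),
        noisy=np.stack([p.noisy for p in pairs]),
        nominal_snr_db=np.array([p.nominal_snr_db for p in pairs]),
        source_id=np.array([p.source_id for p in pairs]),
    )


def load_pairs_npz(path) -> list[SegmentPair]:
    with np.load(path) as data:
        return [
            SegmentPair(
                noisy=data["noisy"][i],
                clean=data["clean"][i],
                nominal_snr_db=float(data["nominal_snr_db"][i]),
                source_id=str(data["source_id"][i]),
            )
            for i in range(data["clean"].shape[0])
        ]


def stack_pairs(
    pairs: Sequence[SegmentPair],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (noisy, clean, nominal_snr_db) as stacked arrays."""
    noisy = np.stack([p.noisy for p in pairs])
    clean = np.stack([p.clean for p in pairs])
    levels = np.array([p.nominal_snr_db for p in pairs])
    return noisy, clean, levels
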