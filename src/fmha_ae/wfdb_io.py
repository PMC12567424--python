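"""Minimal read-only loader for PhysioNet WFDB records.

Supports the header (.hea) layout and the two sample encodings used by the
MIT-BIH Arrhythmia Database and the Noise Stress Test Database: format 212
(two 12-bit two's-complement samples packed into 3 bytes) and format 16
(little-endian int16).  Samples are converted to physical units as
``(adc - baseline) / gain``.  This is a deliberately small reader for the
optional real-data path; it does not write records or read annotations.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = ["WFDBRecord", "read_wfdb_record"]


@dataclasses.dataclass
class WFDBRecord:
    name: str
    sampling_rate: float
    signal_names: list[str]
    signals: np.ndarray  # (n_samples, n_channels), physical units


def _decode_212(raw: np.ndarray, n_samples_total: int) -> np.ndarray:
    raw = raw[: (len(raw) // 3) * 3].reshape(-1, 3).astype(np.int32)
    first = ((raw[:, 1] & 0x0F) << 8) | raw[:, 0]
    second = ((raw[:, 1] & 0xF0) << 4) | raw[:, 2]
    samples = np.empty(2 * len(raw), dtype=np.int32)
    samples[0::2] = first
    samples[1::2] = second
    samples[samples > 2047] -= 4096  # 12-bit two's complement
    return samples[:n_samples_total]


def read_wfdb_record(
    path_prefix, channels: Optional[Sequence[str]] = None
) -> WFDBRecord:
    """Read ``<path_prefix>.hea`` + ``<path_prefix>.dat``.

    Parameters
    ----------
    path_prefix : path to the record without extension (e.g. ``.../118``).
    channels : optional list of signal names (e.g. ``["MLII"]``) to select;
        default is all channels, in file order.
    """
    prefix = Path(path_prefix)
    header_path = prefix.with_suffix(".hea")
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    record_name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0

    fmt: list[int] = []
    gains: list[float] = []
    baselines: list[int] = []
    names: list[str] = []
    dat_files: list[str] = []
    for spec in lines[1 : 1 + n_sig]:
        fields = spec.split()
        dat_files.append(fields[0])
        fmt.append(int(fields[1].split("x")[0].split(":")[0].split("+")[0]))
        gain_field = fields[2] if len(fields) > 2 else "200"
        gain_str = gain_field.split("/")[0]
        if "(" in gain_str:
            gain, base = gain_str.split("(")
            gains.append(float(gain))
            baselines.append(int(base.rstrip(")")))
        else:
            gains.append(float(gain_str))
            # ADC zero (field 5) doubles as baseline when no "(baseline)"
            baselines.append(int(fields[4]) if len(fields) > 4 else 0)
        names.append(fields[-1] if len(fields) > 8 else f"ch{len(names)}")

    if len(set(dat_files)) != 1:
        raise NotImplementedError("multi-file WFDB records are not supported")
    if len(set(fmt)) != 1:
        raise NotImplementedError("mixed sample formats are not supported")
    data_path = prefix.parent / dat_files[0]
    raw = np.fromfile(data_path, dtype=np.uint8)

    if fmt[0] == 212:
        flat = _decode_212(raw, n_samples * n_sig if n_samples else len(raw))
    elif fmt[0] == 16:
        flat = raw.view("<i2").astype(np.int32)
        if n_samples:
            flat = flat[: n_samples * n_sig]
    else:
        raise NotImplementedError(f"WFDB sample format {fmt[0]} not supported")

    adc = flat.reshape(-1, n_sig)
    physical = (adc - np.array(baselines)) / np.array(gains)

    if channels is not None:
        missing = [c for c in channels if c not in names]
        if missing:
            raise ValueError(f"channels {missing} not in record (has {names})")
        idx = [names.index(c) for c in channels]
        physical = physical[:, idx]
        names = list(channels)

    return WFDBRecord(
        name=record_name,
        sampling_rate=fs,
        signal_names=names,
        signals=physical,
    )
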