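"""Minimal EDF (European Data Format) writer for multichannel EEG.

Writes 16-bit EDF with one data record per second, physical dimension µV.
Only what the pipeline needs: continuous equal-rate signals, ASCII header
per the EDF specification (256-byte fixed header + 256 bytes per signal).
Reading is delegated to MNE elsewhere, which doubles as an independent
check of this writer.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # Trim numeric fields from the right (keeps sign and leading digits).
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> bytes:
    for fmt in (f"{x:.6g}", f"{x:.4g}", f"{x:.3g}", f"{x:.2g}"):
        if len(fmt) <= width:
            return _field(fmt, width)
    return _field(f"{x:.1g}", width)


def write_edf(
    path: str | Path,
    data: np.ndarray,
    channel_labels: list[str],
    sampling_rate_hz: float,
    *,
    physical_dim: str = "uV",
    patient_id: str = "X",
    recording_id: str = "synthetic",
    start_date: str = "01.01.22",
    start_time: str = "12.00.00",
) -> Path:
    """Write an (n_channels, n_samples) µV matrix as 16-bit EDF.

    The sampling rate must be a positive integer (samples per 1-s record).
    Trailing samples beyond a whole number of seconds are dropped.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (n_channels, n_samples)")
    n_channels, n_samples = data.shape
    if len(channel_labels) != n_channels:
        raise ValueError("channel_labels length must match data rows")
    sfreq = int(round(sampling_rate_hz))
    if sfreq <= 0 or abs(sfreq - sampling_rate_hz) > 1e-9:
        raise ValueError("sampling_rate_hz must be a positive integer for EDF records")
    n_records = n_samples // sfreq
    if n_records == 0:
        raise ValueError("recording shorter than one 1-s EDF record")
    data = data[:, : n_records * sfreq]

    # Per-channel physical range, padded so extremes stay inside the range.
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    span = np.maximum(pmax - pmin, 1e-6)
    pmin = pmin - 0.01 * span
    pmax = pmax + 0.01 * span

    header = b""
    header += _field("0", 8)
    header += _field(patient_id, 80)
    header += _field(recording_id, 80)
    header += _field(start_date, 8)
    header += _field(start_time, 8)
    header += _field(256 * (n_channels + 1), 8)
    header += _field("", 44)
    header += _field(n_records, 8)
    header += _field("1", 8)
    header += _field(n_channels, 4)

    def signal_fields(values, width):
        return b"".join(_field(v, width) for v in values)

    header += signal_fields(channel_labels, 16)
    header += signal_fields([""] * n_channels, 80)           # transducer
    header += signal_fields([physical_dim] * n_channels, 8)
    header += b"".join(_fmt_float(v) for v in pmin)
    header += b"".join(_fmt_float(v) for v in pmax)
    header += signal_fields([_DIG_MIN] * n_channels, 8)
    header += signal_fields([_DIG_MAX] * n_channels, 8)
    header += signal_fields([""] * n_channels, 80)           # prefiltering
    header += signal_fields([sfreq] * n_channels, 8)
    header += signal_fields([""] * n_channels, 32)

    # Re-parse the physical range exactly as a reader will, so quantization
    # is computed against the header values actually written.
    pmin_w = np.array([float(_fmt_float(v).decode()) for v in pmin])
    pmax_w = np.array([float(_fmt_float(v).decode()) for v in pmax])
    scale = (_DIG_MAX - _DIG_MIN) / (pmax_w - pmin_w)
    digital = np.round((data - pmin_w[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            block = digital[:, rec * sfreq : (rec + 1) * sfreq]
            fh.write(block.tobytes())  # channel-major within record, per EDF
    return path
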