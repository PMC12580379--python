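"""EEG reading and the resting-state cleaning chain.

Stages (each a pure function on :class:`EEGRecording`):

1. 50 Hz zero-phase notch (2nd-order IIR, Q=30) against line noise
2. 1–45 Hz zero-phase Butterworth band-pass (order 4, forward–backward)
3. bad-channel detection: robust z-score (median/MAD) of per-channel
   temporal SD above a threshold (default 4)
4. dataset exclusion when more than ``max_bad`` channels are bad
5. spherical-spline interpolation of bad channels (Perrin-style, order 4)
6. average re-referencing
7. selection of the n quietest non-overlapping 10-s epochs

An ocular/myogenic artifact-removal stage is deliberately a no-op slot here
(`artifact_removal`): the synthetic data carry no such artifacts; users with
real recordings can plug in their own cleaner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import signal

from .montage import get_montage, positions_array

logger = logging.getLogger(__name__)


@dataclass
class EEGRecording:
    """Multichannel EEG in µV with montage metadata."""

    data: np.ndarray                      # (n_channels, n_samples)
    channel_labels: tuple[str, ...]
    sampling_rate_hz: float
    montage: dict[str, np.ndarray]
    reference: str = "original"           # original | average

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data rows must match channel labels")
        missing = [ch for ch in self.channel_labels if ch not in self.montage]
        if missing:
            raise KeyError(f"montage has no coordinates for channel(s): {missing}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Fixed-length analysis epochs cut from one recording."""

    epochs: list[np.ndarray]              # each (n_channels, n_epoch_samples)
    epoch_length_s: float
    sampling_rate_hz: float
    start_samples: tuple[int, ...]
    channel_labels: tuple[str, ...]

    def __post_init__(self):
        shapes = {e.shape for e in self.epochs}
        if len(shapes) > 1:
            raise ValueError("all epochs must share one shape")

    @property
    def count(self) -> int:
        return len(self.epochs)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, fmt: str = "auto") -> EEGRecording:
    """Read EEG from EDF or a delimited matrix (channels as columns).

    Channel labels must resolve to the built-in 10-20 montage; an unknown
    label raises ``KeyError`` naming the channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown format {fmt!r}; expected edf|delimited")


def _read_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = tuple(raw.ch_names)
    data_uv = raw.get_data() * 1e6  # MNE stores EEG in volts
    montage = get_montage(labels)
    return EEGRecording(data_uv, labels, float(raw.info["sfreq"]), montage)


def _read_delimited(path: Path, sampling_rate_hz: float = 500.0) -> EEGRecording:
    df = pd.read_csv(path, sep=None, engine="python")
    labels = tuple(str(c) for c in df.columns)
    montage = get_montage(labels)
    return EEGRecording(df.to_numpy(float).T, labels, sampling_rate_hz, montage)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _filtfilt(b: np.ndarray, a: np.ndarray, data: np.ndarray) -> np.ndarray:
    padlen = 3 * max(len(a), len(b))
    return signal.filtfilt(b, a, data, axis=-1, padtype="even", padlen=padlen)


def notch_filter(rec: EEGRecording, freq_hz: float = 50.0, quality: float = 30.0) -> EEGRecording:
    """Zero-phase band-stop at the line frequency (2nd-order IIR notch)."""
    nyq = rec.sampling_rate_hz / 2.0
    if not 0 < freq_hz < nyq:
        raise ValueError(f"notch frequency {freq_hz} Hz must be below Nyquist ({nyq} Hz)")
    b, a = signal.iirnotch(freq_hz, quality, fs=rec.sampling_rate_hz)
    out = replace(rec, data=_filtfilt(b, a, rec.data))
    logger.info("notch_filter freq_hz=%s quality=%s", freq_hz, quality)
    return out


def bandpass_filter(
    rec: EEGRecording, lo_hz: float = 1.0, hi_hz: float = 45.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass (forward-backward, effective order 2x)."""
    nyq = rec.sampling_rate_hz / 2.0
    if not 0 < lo_hz < hi_hz < nyq:
        raise ValueError(f"invalid band edges ({lo_hz}, {hi_hz}) for Nyquist {nyq}")
    b, a = signal.butter(order, [lo_hz / nyq, hi_hz / nyq], btype="band")
    out = replace(rec, data=_filtfilt(b, a, rec.data))
    logger.info("bandpass_filter lo_hz=%s hi_hz=%s order=%s", lo_hz, hi_hz, order)
    return out


def artifact_removal(rec: EEGRecording, cleaner=None) -> EEGRecording:
    """Pluggable artifact-removal slot; identity by default.

    Synthetic recordings carry no ocular/myogenic components, so the default
    pipeline performs no source-separation cleaning.  ``cleaner`` may be any
    callable mapping an (n_channels, n_samples) array to a like array.
    """
    if cleaner is None:
        return rec
    return replace(rec, data=np.asarray(cleaner(rec.data), dtype=float))


# ---------------------------------------------------------------------------
# Bad channels
# ---------------------------------------------------------------------------

def detect_bad_channels(rec: EEGRecording, z_threshold: float = 4.0) -> list[str]:
    """Channels whose temporal SD is a robust outlier across channels.

    Per-channel SDs are standardized with the median and the scaled MAD
    (1.4826·MAD); channels with |z| above ``z_threshold`` are flagged.  A raw
    µV threshold of 4 would flag essentially every channel, so the threshold
    is read on this standardized scale.
    """
    if rec.n_channels < 4:
        raise ValueError("need at least 4 channels for robust bad-channel detection")
    sds = rec.data.std(axis=1)
    med = np.median(sds)
    mad = np.median(np.abs(sds - med)) * 1.4826
    if mad == 0:
        return []
    z = (sds - med) / mad
    bad = [ch for ch, zi in zip(rec.channel_labels, z) if abs(zi) > z_threshold]
    logger.info("detect_bad_channels z_threshold=%s flagged=%s", z_threshold, bad)
    return bad


def exclude_if_too_many_bad(bad: list[str], max_bad: int = 2) -> bool:
    """Dataset-exclusion rule: True (exclude) iff more than ``max_bad`` bad channels."""
    return len(bad) > max_bad


# ---------------------------------------------------------------------------
# Spherical-spline interpolation
# ---------------------------------------------------------------------------

def _spline_g(cosang: np.ndarray, order: int = 4, n_terms: int = 50) -> np.ndarray:
    """Spherical-spline kernel g(cos angle) as a truncated Legendre series."""
    n = np.arange(1, n_terms + 1)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * n + 1) / (n * (n + 1)) ** order
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coeffs) / (4.0 * np.pi)


def interpolate_spherical(
    rec: EEGRecording,
    bad: list[str],
    order: int = 4,
    regularization: float = 1e-5,
    n_terms: int = 50,
) -> EEGRecording:
    """Reconstruct bad channels by spherical-spline interpolation.

    Fits a spline over the good electrodes' unit-sphere positions at every
    sample (with a small ridge on the kernel matrix) and evaluates it at the
    bad electrodes.  Good channels are untouched.
    """
    if not bad:
        return rec
    unknown = [ch for ch in bad if ch not in rec.channel_labels]
    if unknown:
        raise KeyError(f"bad channels not in recording: {unknown}")
    good_idx = [i for i, ch in enumerate(rec.channel_labels) if ch not in bad]
    bad_idx = [i for i, ch in enumerate(rec.channel_labels) if ch in bad]
    if len(good_idx) < 4:
        raise ValueError("need at least 4 good channels for spherical interpolation")

    pos = positions_array(rec.montage, list(rec.channel_labels))
    pos_good = pos[good_idx]
    pos_bad = pos[bad_idx]

    G = _spline_g(pos_good @ pos_good.T, order, n_terms)
    G_reg = G + regularization * np.eye(len(good_idx))
    # Spline with a free constant term: [[G, 1], [1^T, 0]] [c; c0] = [v; 0].
    n_good = len(good_idx)
    A = np.zeros((n_good + 1, n_good + 1))
    A[:n_good, :n_good] = G_reg
    A[:n_good, n_good] = 1.0
    A[n_good, :n_good] = 1.0
    rhs = np.vstack([rec.data[good_idx], np.zeros((1, rec.n_samples))])
    sol = np.linalg.solve(A, rhs)
    c, c0 = sol[:n_good], sol[n_good]

    G_bad = _spline_g(pos_bad @ pos_good.T, order, n_terms)
    data = rec.data.copy()
    data[bad_idx] = G_bad @ c + c0
    logger.info("interpolate_spherical bad=%s order=%s reg=%s", bad, order, regularization)
    return replace(rec, data=data)


# ---------------------------------------------------------------------------
# Referencing and epoching
# ---------------------------------------------------------------------------

def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Subtract the per-sample channel mean; idempotent."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data, reference="average")


def select_epochs(rec: EEGRecording, n: int = 5, length_s: float = 10.0) -> EpochSet:
    """The ``n`` quietest non-overlapping windows, in temporal order.

    The recording is partitioned into consecutive candidate windows of
    ``length_s``; each is scored by its total channel variance and the ``n``
    lowest-variance windows are returned.  Deterministic.
    """
    win = int(round(length_s * rec.sampling_rate_hz))
    n_windows = rec.n_samples // win
    if n_windows < n:
        raise ValueError(
            f"recording too short: {rec.n_samples} samples yields {n_windows} "
            f"windows of {length_s}s, need {n}"
        )
    scores = []
    for w in range(n_windows):
        seg = rec.data[:, w * win : (w + 1) * win]
        scores.append(seg.var(axis=1).sum())
    chosen = sorted(np.argsort(scores)[:n])
    starts = tuple(int(w * win) for w in chosen)
    epochs = [rec.data[:, s : s + win].copy() for s in starts]
    logger.info("select_epochs n=%s length_s=%s starts=%s", n, length_s, starts)
    return EpochSet(epochs, length_s, rec.sampling_rate_hz, starts, rec.channel_labels)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    """Outcome of the cleaning chain for one recording."""

    epochs: EpochSet | None
    bad_channels: list[str]
    excluded: bool


def preprocess(
    rec: EEGRecording,
    *,
    notch_hz: float = 50.0,
    band: tuple[float, float] = (1.0, 45.0),
    filter_order: int = 4,
    bad_z_threshold: float = 4.0,
    max_bad_channels: int = 2,
    n_epochs: int = 5,
    epoch_length_s: float = 10.0,
    bad_detection: str = "post_filter",
    cleaner=None,
) -> PreprocessResult:
    """Run the full cleaning chain; returns None epochs if excluded.

    ``bad_detection`` chooses whether the SD criterion is evaluated before
    or after filtering (``pre_filter`` | ``post_filter``).
    """
    if bad_detection not in ("pre_filter", "post_filter"):
        raise ValueError("bad_detection must be pre_filter|post_filter")
    bad_pre = detect_bad_channels(rec, bad_z_threshold) if bad_detection == "pre_filter" else None
    rec = notch_filter(rec, notch_hz)
    rec = artifact_removal(rec, cleaner)
    rec = bandpass_filter(rec, band[0], band[1], filter_order)
    bad = bad_pre if bad_pre is not None else detect_bad_channels(rec, bad_z_threshold)
    if exclude_if_too_many_bad(bad, max_bad_channels):
        logger.info("preprocess excluded: %d bad channels %s", len(bad), bad)
        return PreprocessResult(None, bad, True)
    rec = interpolate_spherical(rec, bad)
    rec = rereference_average(rec)
    epochs = select_epochs(rec, n_epochs, epoch_length_s)
    return PreprocessResult(epochs, bad, False)
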