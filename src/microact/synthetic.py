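"""Synthetic EEG and actigraphy with known ground truth.

Every downstream stage of the pipeline (preprocessing, microstate analysis,
actigraphy metrics, statistics) is testable against data generated here:

* **EEG**: at each instant the scalp topography is one of K fixed template
  maps scaled by a fluctuating positive amplitude envelope, plus spatially
  correlated noise.  States follow a semi-Markov process: geometric dwell
  times (tens of ms) and a row-stochastic matrix over *distinct* next states.
* **Actigraphy**: paired per-minute lognormal count series with a Gaussian
  copula tuned per realization so the empirical inter-arm Pearson r hits its
  target, then globally rescaled so the affected/unaffected count-sum ratio
  (ULAR) hits its target exactly.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import time as dtime
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, signal
from scipy.special import ndtri

from .actigraphy import ActigraphyPair
from .montage import DEFAULT_CHANNELS, cosine_distances, get_montage, positions_array

STATE_LABELS = ("A", "B", "C", "D", "E", "F", "G", "H")


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

@dataclass
class MicrostateTemplateSet:
    """K topographic template maps: zero-mean, unit-norm rows."""

    maps: np.ndarray            # (k, n_channels)
    labels: tuple[str, ...]
    n_channels: int

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[1] != self.n_channels:
            raise ValueError("maps must be (k, n_channels)")
        row_means = self.maps.mean(axis=1)
        row_norms = np.linalg.norm(self.maps, axis=1)
        if np.any(np.abs(row_means) > 1e-9) or np.any(np.abs(row_norms - 1) > 1e-9):
            raise ValueError("template rows must be zero-mean and unit-norm")

    @property
    def k(self) -> int:
        return self.maps.shape[0]


def _spatial_abs_corr(maps: np.ndarray) -> np.ndarray:
    centered = maps - maps.mean(axis=1, keepdims=True)
    normed = centered / np.linalg.norm(centered, axis=1, keepdims=True)
    return np.abs(normed @ normed.T)


def generate_templates(
    n_channels: int = 19,
    k: int = 4,
    montage: dict[str, np.ndarray] | None = None,
    seed: int | None = None,
    max_pairwise_corr: float = 0.8,
) -> MicrostateTemplateSet:
    """Random smooth dipolar-looking template maps.

    Each map is a linear spatial gradient over the 3-D electrode positions
    along a randomly oriented axis, average-referenced and normalized; maps
    are redrawn until all pairwise absolute spatial correlations fall below
    ``max_pairwise_corr`` so the templates are distinguishable.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_channels - 1:
        raise ValueError(
            f"k={k} templates cannot be distinguishable with {n_channels} "
            "average-referenced channels (need k <= n_channels - 1)"
        )
    if montage is None:
        montage = get_montage(DEFAULT_CHANNELS[:n_channels])
    pos = positions_array(montage)
    if pos.shape[0] != n_channels:
        raise ValueError("montage size must match n_channels")
    rng = np.random.default_rng(seed)
    maps: list[np.ndarray] = []
    for _ in range(k):
        for _attempt in range(1000):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            m = pos @ direction
            m = m - m.mean()
            norm = np.linalg.norm(m)
            if norm < 1e-12:
                continue
            m /= norm
            if all(abs(m @ prev) < max_pairwise_corr for prev in maps):
                maps.append(m)
                break
        else:  # pragma: no cover - only reachable with absurd max_corr
            raise RuntimeError("could not draw distinguishable templates")
    return MicrostateTemplateSet(np.array(maps), STATE_LABELS[:k], n_channels)


# ---------------------------------------------------------------------------
# State sequences
# ---------------------------------------------------------------------------

def uniform_transition_matrix(k: int) -> np.ndarray:
    """Row-stochastic matrix with zero diagonal and uniform off-diagonal mass."""
    if k < 2:
        raise ValueError("need at least 2 states")
    P = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(P, 0.0)
    return P


@dataclass
class StateSequenceSpec:
    """Semi-Markov state sequence specification.

    ``transition_matrix`` is the embedded chain over *distinct* next states
    (zero diagonal); dwell times are geometric on samples with mean
    ``mean_dwell_ms`` per state.
    """

    k: int = 4
    transition_matrix: np.ndarray | None = None
    mean_dwell_ms: float | np.ndarray = 60.0
    sampling_rate_hz: float = 500.0
    total_duration_s: float = 50.0
    seed: int | None = None

    def __post_init__(self):
        if self.transition_matrix is None:
            self.transition_matrix = uniform_transition_matrix(self.k)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        P = self.transition_matrix
        if P.shape != (self.k, self.k):
            raise ValueError("transition_matrix must be (k, k)")
        if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition_matrix rows must sum to 1")
        if np.any(np.abs(np.diag(P)) > 0):
            raise ValueError("transition_matrix diagonal must be 0 (no self-transitions)")
        dwell = np.broadcast_to(np.asarray(self.mean_dwell_ms, dtype=float), (self.k,)).copy()
        min_dwell = 2.0 * 1000.0 / self.sampling_rate_hz
        if np.any(dwell <= min_dwell):
            raise ValueError(
                f"mean_dwell_ms must exceed {min_dwell:.3f} ms (two samples) per state"
            )
        self.mean_dwell_ms = dwell

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_s * self.sampling_rate_hz))

    @property
    def mean_dwell_samples(self) -> np.ndarray:
        return self.mean_dwell_ms * self.sampling_rate_hz / 1000.0


def stationary_distribution(spec: StateSequenceSpec) -> np.ndarray:
    """Long-run fraction of time per state (embedded chain weighted by dwell)."""
    P = spec.transition_matrix
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    nu = np.real(vecs[:, i])
    nu = np.abs(nu) / np.abs(nu).sum()
    pi = nu * spec.mean_dwell_samples
    return pi / pi.sum()


def simulate_state_sequence(spec: StateSequenceSpec) -> np.ndarray:
    """Per-sample state indices from the alternating-renewal process."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    p_leave = 1.0 / spec.mean_dwell_samples
    labels = np.empty(n, dtype=np.int64)
    state = int(rng.integers(spec.k))
    pos = 0
    while pos < n:
        dwell = int(rng.geometric(p_leave[state]))
        labels[pos : pos + dwell] = state
        pos += dwell
        state = int(rng.choice(spec.k, p=spec.transition_matrix[state]))
    return labels


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

@dataclass
class SyntheticEEG:
    """Generated EEG with ground truth attached."""

    data: np.ndarray                    # (n_channels, n_samples), µV
    truth_labels: np.ndarray            # (n_samples,)
    truth_templates: MicrostateTemplateSet
    snr: float
    sampling_rate_hz: float
    channel_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.channel_labels is None:
            self.channel_labels = DEFAULT_CHANNELS[: self.data.shape[0]]


def synthesize_eeg(
    templates: MicrostateTemplateSet,
    labels: np.ndarray,
    sampling_rate_hz: float = 500.0,
    snr: float = 4.0,
    seed: int | None = None,
    *,
    amplitude_uv: float = 30.0,
    carrier_band_hz: tuple[float, float] = (8.0, 13.0),
    noise_smoothness_rad: float = 0.35,
    montage: dict[str, np.ndarray] | None = None,
) -> SyntheticEEG:
    """Template topographies modulated by an alpha-band carrier, plus noise.

    ``data[:, t] = amplitude_uv * a(t) * templates.maps[labels[t]] + noise``
    where ``a(t)`` is a zero-mean narrowband Gaussian oscillation
    (Butterworth band-pass of white noise over ``carrier_band_hz``,
    RMS-normalized).  This mimics resting-state EEG: power concentrated in
    the alpha band, GFP peaking twice per cycle at the carrier extrema, and
    the topography's polarity flipping with the carrier sign — the reason
    microstate clustering ignores polarity.  The noise is spatially smoothed
    Gaussian noise, average-referenced, scaled so the state-signal RMS over
    noise RMS equals ``snr``.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() < 0 or labels.max() >= templates.k:
        raise ValueError("labels must index into templates")
    n_channels = templates.n_channels
    n = len(labels)
    rng = np.random.default_rng(seed)

    nyq = sampling_rate_hz / 2.0
    b, a = signal.butter(2, [carrier_band_hz[0] / nyq, carrier_band_hz[1] / nyq], "band")
    carrier = signal.filtfilt(b, a, rng.standard_normal(n))
    carrier /= np.sqrt(np.mean(carrier**2))

    S = (templates.maps[labels] * carrier[:, None]).T * amplitude_uv

    if montage is None:
        montage = get_montage(DEFAULT_CHANNELS[:n_channels])
    pos = positions_array(montage)
    D = cosine_distances(pos)
    W = np.exp(-(D**2) / (2.0 * noise_smoothness_rad**2))
    noise = W @ rng.standard_normal((n_channels, n))
    noise -= noise.mean(axis=0, keepdims=True)  # keep average-reference invariant
    rms_signal = float(np.sqrt(np.mean(S**2)))
    rms_noise = float(np.sqrt(np.mean(noise**2)))
    noise *= rms_signal / (snr * rms_noise)

    return SyntheticEEG(
        data=S + noise,
        truth_labels=labels,
        truth_templates=templates,
        snr=snr,
        sampling_rate_hz=sampling_rate_hz,
        channel_labels=DEFAULT_CHANNELS[:n_channels],
    )


# ---------------------------------------------------------------------------
# Actigraphy synthesis
# ---------------------------------------------------------------------------

@dataclass
class SyntheticActigraphySpec:
    """Paired per-minute count series with controlled statistical structure.

    The unaffected arm follows a lognormal per-minute count process whose
    location is set so that ``frac_moderate`` of minutes exceed
    ``moderate_threshold``; the affected arm is a copula-correlated copy
    rescaled to the target ULAR.
    """

    n_minutes: int = 1440
    target_r: float = 0.62
    target_ular_pct: float = 30.0
    moderate_threshold: float = 500.0
    frac_moderate: float = 0.15
    sigma_log: float = 1.0
    day_start: dtime = dtime(6, 0)
    night_start: dtime = dtime(22, 0)
    start_timestamp: str = "2022-01-01 12:00:00"
    seed: int | None = None

    def __post_init__(self):
        if self.n_minutes < 60:
            raise ValueError("n_minutes must be >= 60")
        if not -1.0 <= self.target_r <= 1.0:
            raise ValueError("target_r must lie in [-1, 1]")
        if self.target_ular_pct <= 0:
            raise ValueError("target_ular_pct must be positive")
        if not 0.0 < self.frac_moderate < 1.0:
            raise ValueError("frac_moderate must lie in (0, 1)")
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be positive")


@dataclass
class ActigraphySynthesis:
    """Generated pair plus the metrics the generator actually achieved."""

    pair: ActigraphyPair
    spec: SyntheticActigraphySpec
    achieved_r: float
    achieved_ular_pct: float
    achieved_frac_moderate_unaffected: float
    achieved_frac_moderate_affected: float
    copula_rho: float


def synthesize_actigraphy(spec: SyntheticActigraphySpec) -> ActigraphySynthesis:
    """Generate the pair; tune the copula against the empirical Pearson r.

    Infeasible (target_r, marginal) combinations — lognormal pairs cannot be
    arbitrarily anticorrelated — are clamped to the nearest achievable value
    with a fit-quality warning.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_minutes
    sigma = spec.sigma_log
    mu = np.log(spec.moderate_threshold) - sigma * ndtri(1.0 - spec.frac_moderate)

    z1 = rng.standard_normal(n)
    e = rng.standard_normal(n)
    unaffected = np.exp(mu + sigma * z1)

    def affected_raw(rho: float) -> np.ndarray:
        z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * e
        return np.exp(mu + sigma * z2)

    def emp_r(rho: float) -> float:
        return float(np.corrcoef(affected_raw(rho), unaffected)[0, 1])

    lo, hi = -0.9999, 0.9999
    if spec.target_r >= emp_r(hi):
        rho = 1.0
        if spec.target_r < 0.999:
            warnings.warn(
                f"target_r={spec.target_r} above achievable range; using rho=1",
                RuntimeWarning,
            )
    elif spec.target_r <= emp_r(lo):
        rho = lo
        warnings.warn(
            f"target_r={spec.target_r} below achievable range for lognormal "
            f"marginals (min {emp_r(lo):.3f}); clamped",
            RuntimeWarning,
        )
    else:
        rho = float(optimize.brentq(lambda r: emp_r(r) - spec.target_r, lo, hi, xtol=1e-10))

    affected = affected_raw(rho) if rho < 1.0 else unaffected.copy()
    scale = (spec.target_ular_pct / 100.0) * unaffected.sum() / affected.sum()
    affected *= scale

    timestamps = pd.date_range(spec.start_timestamp, periods=n, freq="min")
    pair = ActigraphyPair(
        timestamps,
        affected,
        unaffected,
        day_start=spec.day_start,
        night_start=spec.night_start,
    )
    return ActigraphySynthesis(
        pair=pair,
        spec=spec,
        achieved_r=float(np.corrcoef(affected, unaffected)[0, 1]),
        achieved_ular_pct=float(affected.sum() / unaffected.sum() * 100.0),
        achieved_frac_moderate_unaffected=float(np.mean(unaffected > spec.moderate_threshold)),
        achieved_frac_moderate_affected=float(np.mean(affected > spec.moderate_threshold)),
        copula_rho=rho,
    )


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------

#: Cohort summary statistics used as generator defaults (age in years; scales
#: in their clinical ranges).  Patients and controls differ only in age/sex
#: composition; clinical scores exist for patients.
COHORT_DEFAULTS = {
    "n_patients": 34,
    "n_controls": 50,
    "age_patients": (62.44, 9.76),
    "age_controls": (59.58, 9.15),
    "male_frac_patients": 21 / 34,
    "male_frac_controls": 25 / 50,
    "nihss": (6.53, 3.40),
    "fma": (50.12, 20.30),
    "moca": (19.60, 5.54),
    "mmse": (21.44, 4.38),
    "mrs_90d": (1.68, 1.00),
    "right_paresis_frac": 20 / 34,
}


def synthesize_clinical_table(
    n_patients: int | None = None,
    n_controls: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-subject clinical covariates table for a synthetic cohort.

    Columns: subject_id, group (CI|HC), age, sex (1=male), and for patients
    NIHSS, FMA, MoCA, MMSE, mRS at 90 days, affected_side (left|right).
    """
    d = COHORT_DEFAULTS
    n_patients = d["n_patients"] if n_patients is None else n_patients
    n_controls = d["n_controls"] if n_controls is None else n_controls
    rng = np.random.default_rng(seed)

    def clipped_normal(mean_sd, n, lo, hi, integer=False):
        x = np.clip(rng.normal(*mean_sd, size=n), lo, hi)
        return np.round(x).astype(int) if integer else np.round(x, 2)

    rows = []
    for i in range(n_patients):
        rows.append(
            {
                "subject_id": f"CI{i + 1:03d}",
                "group": "CI",
                "age": float(np.clip(rng.normal(*d["age_patients"]), 30, 80)),
                "sex": int(rng.random() < d["male_frac_patients"]),
            }
        )
    for i in range(n_controls):
        rows.append(
            {
                "subject_id": f"HC{i + 1:03d}",
                "group": "HC",
                "age": float(np.clip(rng.normal(*d["age_controls"]), 30, 80)),
                "sex": int(rng.random() < d["male_frac_controls"]),
            }
        )
    columns = ["subject_id", "group", "age", "sex", "nihss", "fma", "moca", "mmse",
               "mrs_90d", "affected_side"]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    pat = df["group"] == "CI"
    n_p = int(pat.sum())
    df.loc[pat, "nihss"] = clipped_normal(d["nihss"], n_p, 0, 42, integer=True)
    df.loc[pat, "fma"] = clipped_normal(d["fma"], n_p, 0, 66, integer=True)
    df.loc[pat, "moca"] = clipped_normal(d["moca"], n_p, 0, 30, integer=True)
    df.loc[pat, "mmse"] = clipped_normal(d["mmse"], n_p, 0, 30, integer=True)
    df.loc[pat, "mrs_90d"] = clipped_normal(d["mrs_90d"], n_p, 0, 5, integer=True)
    df.loc[pat, "affected_side"] = np.where(
        rng.random(n_p) < d["right_paresis_frac"], "right", "left"
    )
    df["age"] = df["age"].round(2)
    return df


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_eeg_delimited(path: str | Path, eeg: SyntheticEEG, sep: str = "\t") -> Path:
    """Plain delimited matrix: channels as columns with a 10-20 label header."""
    df = pd.DataFrame(eeg.data.T, columns=list(eeg.channel_labels))
    path = Path(path)
    df.to_csv(path, sep=sep, index=False, float_format="%.6f")
    return path


def write_eeg_edf(path: str | Path, eeg: SyntheticEEG) -> Path:
    """16-bit EDF export in physical units µV."""
    from .edf import write_edf

    return write_edf(
        path, eeg.data, list(eeg.channel_labels), eeg.sampling_rate_hz
    )


def write_truth_sidecar(path: str | Path, eeg: SyntheticEEG, spec: StateSequenceSpec) -> Path:
    """Ground-truth sidecar (templates, labels, sequence spec) as JSON."""
    payload = {
        "templates": eeg.truth_templates.maps.tolist(),
        "template_labels": list(eeg.truth_templates.labels),
        "channel_labels": list(eeg.channel_labels),
        "truth_labels": eeg.truth_labels.tolist(),
        "snr": eeg.snr,
        "sampling_rate_hz": eeg.sampling_rate_hz,
        "sequence_spec": {
            "k": spec.k,
            "transition_matrix": spec.transition_matrix.tolist(),
            "mean_dwell_ms": np.asarray(spec.mean_dwell_ms).tolist(),
            "sampling_rate_hz": spec.sampling_rate_hz,
            "total_duration_s": spec.total_duration_s,
            "seed": spec.seed,
        },
    }
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def load_truth_sidecar(path: str | Path) -> dict:
    """Load a ground-truth sidecar written by :func:`write_truth_sidecar`."""
    payload = json.loads(Path(path).read_text())
    payload["templates"] = np.array(payload["templates"])
    payload["truth_labels"] = np.array(payload["truth_labels"], dtype=np.int64)
    return payload
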