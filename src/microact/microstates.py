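"""EEG microstate segmentation and temporal-dynamics parameters.

The analysis follows the standard resting-state microstate recipe:

1. **GFP** — global field power, the spatial SD of the scalp potential per
   sample (population convention, divide by n).
2. **GFP peaks** — strict local maxima; topographies there have the best
   signal-to-noise and are fed to clustering.
3. **Polarity-invariant modified k-means** — assignment by squared spatial
   correlation |corr|² (maps are average-referenced, so spatial correlation
   equals cosine similarity); centroid update by the first principal
   component of the assigned maps (sign-indeterminate); objective is the
   GFP²-weighted global explained variance (GEV); best of several random
   restarts.
4. **Group mean maps** — permutation/polarity alignment (Hungarian) of
   per-subject maps to a reference, then channel-wise averaging.
5. **Canonical labels** — Hungarian matching to built-in A–D topographies
   (A: right-frontal/left-posterior diagonal, B: mirrored, C: symmetric
   frontal–occipital, D: fronto-central vs peripheral).
6. **Back-fitting** — every sample labeled by its best |corr| map; no
   temporal smoothing by default (optional minimum-duration merge).
7. **Parameters** — coverage, mean duration, occurrence per second, and
   conditional transition probabilities between distinct states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .montage import DEFAULT_CHANNELS, get_montage, positions_array
from .preprocessing import EpochSet
from .synthetic import MicrostateTemplateSet

CANONICAL_LABELS = ("A", "B", "C", "D")


# ---------------------------------------------------------------------------
# GFP
# ---------------------------------------------------------------------------

@dataclass
class GFPSeries:
    """Global field power per sample, with optional detected peaks."""

    values: np.ndarray
    peak_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def compute_gfp(epoch: np.ndarray) -> GFPSeries:
    """Spatial standard deviation across electrodes at each sample.

    GFP(t) = sqrt( sum_i (v_i(t) - vbar(t))^2 / n ), the population SD over
    the n electrodes.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] < 2:
        raise ValueError("epoch must be (n_channels >= 2, n_samples)")
    centered = epoch - epoch.mean(axis=0, keepdims=True)
    return GFPSeries(np.sqrt((centered**2).mean(axis=0)))


def find_gfp_peaks(gfp: GFPSeries, min_separation_samples: int = 0) -> np.ndarray:
    """Strict local maxima of the GFP series; endpoints are never peaks.

    With ``min_separation_samples`` > 0, peaks are greedily accepted in
    decreasing GFP order and any peak closer than the separation to an
    accepted one is dropped (the larger peak wins).  Plateaus produce no
    peak under the strict > rule.
    """
    v = gfp.values
    if len(v) < 3:
        raise ValueError("need at least 3 samples to find peaks")
    interior = np.arange(1, len(v) - 1)
    is_peak = (v[interior] > v[interior - 1]) & (v[interior] > v[interior + 1])
    peaks = interior[is_peak]
    if min_separation_samples > 0 and len(peaks) > 1:
        order = peaks[np.argsort(v[peaks])[::-1]]
        kept: list[int] = []
        for p in order:
            if all(abs(p - q) >= min_separation_samples for q in kept):
                kept.append(int(p))
        peaks = np.array(sorted(kept), dtype=int)
    gfp.peak_indices = peaks
    return peaks


# ---------------------------------------------------------------------------
# Modified k-means
# ---------------------------------------------------------------------------

@dataclass
class MicrostateModel:
    """K template maps with fit diagnostics."""

    maps: np.ndarray                     # (k, n_channels) zero-mean, unit-norm
    gev: float
    k: int
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.shape[0] != self.k:
            raise ValueError("maps rows must equal k")


def _normalize_rows(maps: np.ndarray) -> np.ndarray:
    centered = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate (zero-norm) map")
    return centered / norms


def _principal_map(rows: np.ndarray) -> np.ndarray:
    """First principal component of a set of maps (sign-indeterminate)."""
    S = rows.T @ rows
    vals, vecs = np.linalg.eigh(S)
    v = vecs[:, -1]
    return v / np.linalg.norm(v)


def modified_kmeans(
    peak_maps: np.ndarray,
    k: int = 4,
    n_restarts: int = 50,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int | None = None,
) -> MicrostateModel:
    """Polarity-invariant k-means on GFP-peak topographies.

    Assignment maximizes squared spatial correlation with the centroids;
    the centroid update is the first principal component of the assigned
    maps.  The run maximizing GFP²-weighted GEV over ``n_restarts`` random
    initializations wins.  Empty clusters are re-seeded from the
    worst-explained map.  Deterministic given ``seed``.
    """
    X = np.asarray(peak_maps, dtype=float)
    P = X.shape[0]
    if P < k:
        raise ValueError(f"need at least k={k} maps, got {P}")
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("peak maps must have nonzero norm")
    Xn = X / norms[:, None]
    w = norms**2                     # proportional to GFP² at the peaks
    w_total = w.sum()
    rng = np.random.default_rng(seed)

    best_gev = -np.inf
    best_maps = None
    for _ in range(n_restarts):
        C = Xn[rng.choice(P, size=k, replace=False)].copy()
        prev = -np.inf
        for _it in range(max_iter):
            corr = Xn @ C.T                       # (P, k) cosine similarities
            assign = np.argmax(corr**2, axis=1)
            amax = corr[np.arange(P), assign]
            explained = w * amax**2
            for j in range(k):
                members = assign == j
                if not members.any():
                    C[j] = Xn[int(np.argmin(explained))]
                    continue
                C[j] = _principal_map(X[members])
            corr = Xn @ C.T
            assign = np.argmax(corr**2, axis=1)
            gev = float((w * corr[np.arange(P), assign] ** 2).sum() / w_total)
            if gev - prev < tol:
                break
            prev = gev
        if gev > best_gev:
            best_gev = gev
            best_maps = C.copy()

    return MicrostateModel(maps=_normalize_rows(best_maps), gev=best_gev, k=k)


def compute_gev(
    maps: MicrostateModel | np.ndarray,
    data: np.ndarray | list[np.ndarray],
    assignment: np.ndarray | list[np.ndarray],
) -> float:
    """GFP²-weighted fraction of topographic variance explained by the labeling.

    GEV = sum_t (GFP(t) · corr(v(t), map_{label(t)}))² / sum_t GFP(t)².
    """
    M = maps.maps if isinstance(maps, MicrostateModel) else np.asarray(maps, float)
    Mn = _normalize_rows(M)
    if isinstance(data, np.ndarray):
        data = [data]
        assignment = [np.asarray(assignment)]
    num = 0.0
    den = 0.0
    for V, lab in zip(data, assignment):
        Vc = V - V.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(Vc, axis=0)
        safe = np.where(norms == 0, 1.0, norms)
        cos = np.sum((Vc / safe) * Mn[np.asarray(lab)].T, axis=0)
        num += float(np.sum((norms * cos) ** 2))
        den += float(np.sum(norms**2))
    return num / den if den > 0 else 0.0


# ---------------------------------------------------------------------------
# Group aggregation and canonical labeling
# ---------------------------------------------------------------------------

def _align(reference: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Permute and sign-flip ``maps`` to best match ``reference`` rows."""
    corr = _normalize_rows(reference) @ _normalize_rows(maps).T
    rows, cols = linear_sum_assignment(-np.abs(corr))
    aligned = maps[cols].copy()
    signs = np.sign(corr[rows, cols])
    signs[signs == 0] = 1.0
    return aligned * signs[:, None]


def aggregate_group_maps(models: list[MicrostateModel]) -> MicrostateModel:
    """Mean maps across subjects after permutation/polarity alignment.

    Each model is aligned to the first model's maps by Hungarian assignment
    maximizing total absolute spatial correlation (polarity flipped to the
    positive-correlation orientation), then maps are averaged channel-wise
    and renormalized.
    """
    if not models:
        raise ValueError("no models to aggregate")
    k = models[0].k
    n_ch = models[0].maps.shape[1]
    for m in models:
        if m.k != k or m.maps.shape[1] != n_ch:
            raise ValueError("all models must share k and channel count")
    reference = models[0].maps
    stacked = np.array([_align(reference, m.maps) for m in models])
    mean_maps = _normalize_rows(stacked.mean(axis=0))
    gev = float(np.mean([m.gev for m in models]))
    return MicrostateModel(maps=mean_maps, gev=gev, k=k)


def canonical_templates(
    montage: dict[str, np.ndarray] | None = None,
) -> MicrostateTemplateSet:
    """Built-in idealized A-D topographies on the 19-channel 10-20 montage.

    Constructed as spatial gradients over the electrode positions (head
    frame: +x right, +y anterior, +z superior): A along the right-frontal to
    left-posterior diagonal, B mirrored, C anterior-posterior, D vertical
    (fronto-central maximum vs peripheral).
    """
    if montage is None:
        montage = get_montage(DEFAULT_CHANNELS)
    pos = positions_array(montage)
    directions = {
        "A": np.array([1.0, 1.0, 0.0]) / np.sqrt(2),
        "B": np.array([-1.0, 1.0, 0.0]) / np.sqrt(2),
        "C": np.array([0.0, 1.0, 0.0]),
        "D": np.array([0.0, 0.4, 1.0]) / np.linalg.norm([0.0, 0.4, 1.0]),
    }
    maps = []
    for d in directions.values():
        m = pos @ d
        m -= m.mean()
        maps.append(m / np.linalg.norm(m))
    return MicrostateTemplateSet(np.array(maps), CANONICAL_LABELS, pos.shape[0])


def assign_canonical_labels(
    model: MicrostateModel, canonical: MicrostateTemplateSet | None = None
) -> MicrostateModel:
    """Order and label model maps as A-D by best match to canonical maps.

    Hungarian assignment maximizes summed absolute spatial correlation
    (polarity ignored); rows are reordered into canonical label order.  Ties
    resolve deterministically by smallest label index.
    """
    if canonical is None:
        canonical = canonical_templates()
    if model.k != canonical.k:
        raise ValueError(f"model has k={model.k}, canonical set has {canonical.k}")
    corr = _normalize_rows(canonical.maps) @ _normalize_rows(model.maps).T
    rows, cols = linear_sum_assignment(-np.abs(corr))
    order = cols[np.argsort(rows)]
    return MicrostateModel(
        maps=model.maps[order],
        gev=model.gev,
        k=model.k,
        labels=tuple(canonical.labels[: model.k]),
    )


# ---------------------------------------------------------------------------
# Back-fitting and parameters
# ---------------------------------------------------------------------------

@dataclass
class LabeledSegmentation:
    """Per-sample state labels per epoch plus the derived maximal runs."""

    labels: list[np.ndarray]                       # per epoch (n_samples,)
    segments: list[list[tuple[int, int, int]]]     # per epoch (state, start, length)
    sampling_rate_hz: float
    k: int


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal labels as (state, start, length)."""
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def backfit(
    epochs: EpochSet | list[np.ndarray],
    model: MicrostateModel,
    sampling_rate_hz: float | None = None,
    min_duration_ms: float = 0.0,
) -> LabeledSegmentation:
    """Assign every sample to the map with the highest |spatial correlation|.

    No temporal smoothing by default.  With ``min_duration_ms`` > 0, runs
    shorter than the minimum are absorbed into whichever neighboring state
    correlates better at each sample (applied iteratively shortest-first).
    """
    if isinstance(epochs, EpochSet):
        mats = epochs.epochs
        rate = epochs.sampling_rate_hz
    else:
        mats = list(epochs)
        if sampling_rate_hz is None:
            raise ValueError("sampling_rate_hz required for raw epoch lists")
        rate = sampling_rate_hz
    Mn = _normalize_rows(model.maps)
    all_labels = []
    all_segments = []
    for V in mats:
        Vc = V - V.mean(axis=0, keepdims=True)
        corr = Mn @ Vc                                # (k, n_samples)
        labels = np.argmax(np.abs(corr), axis=0).astype(np.int64)
        if min_duration_ms > 0:
            labels = _merge_short_runs(labels, np.abs(corr), min_duration_ms, rate)
        all_labels.append(labels)
        all_segments.append(_runs(labels))
    return LabeledSegmentation(all_labels, all_segments, rate, model.k)


def _merge_short_runs(
    labels: np.ndarray, abs_corr: np.ndarray, min_duration_ms: float, rate: float
) -> np.ndarray:
    min_len = int(np.ceil(min_duration_ms * rate / 1000.0))
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        for state, start, length in sorted(_runs(labels), key=lambda r: r[2]):
            if length >= min_len:
                continue
            left = labels[start - 1] if start > 0 else None
            right = labels[start + length] if start + length < len(labels) else None
            if left is None and right is None:
                continue
            for t in range(start, start + length):
                cands = [s for s in (left, right) if s is not None]
                labels[t] = max(cands, key=lambda s: abs_corr[s, t])
            changed = True
            break
    return labels


@dataclass
class MicrostateParameters:
    """Temporal-dynamics summaries of one segmentation."""

    coverage: np.ndarray                 # fraction of samples per state
    duration_ms: np.ndarray              # mean run length per state
    occurrence_per_s: np.ndarray         # runs per second per state
    transition: np.ndarray               # (k, k) conditional P(next=s' | leave s)
    transition_defined: np.ndarray       # per-state bool: any run with a successor


def compute_parameters(seg: LabeledSegmentation, k: int | None = None) -> MicrostateParameters:
    """Coverage, duration, occurrence and distinct-state transition matrix.

    Transitions count a run of s immediately followed by a run of s' within
    the same epoch; epoch-final runs contribute no transition.  Rows for
    states without any successor are NaN and flagged undefined rather than
    zero-filled.  States absent from the segmentation get coverage,
    duration and occurrence 0.
    """
    if k is None:
        k = seg.k
    total_samples = sum(len(lab) for lab in seg.labels)
    if total_samples == 0:
        raise ValueError("empty segmentation")
    total_seconds = total_samples / seg.sampling_rate_hz

    sample_counts = np.zeros(k)
    run_counts = np.zeros(k)
    run_length_sums = np.zeros(k)
    trans_counts = np.zeros((k, k))
    for labels, segments in zip(seg.labels, seg.segments):
        for i, (state, _start, length) in enumerate(segments):
            sample_counts[state] += length
            run_counts[state] += 1
            run_length_sums[state] += length
            if i + 1 < len(segments):
                trans_counts[state, segments[i + 1][0]] += 1

    coverage = sample_counts / total_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_len = np.where(run_counts > 0, run_length_sums / np.maximum(run_counts, 1), 0.0)
    duration_ms = mean_len * 1000.0 / seg.sampling_rate_hz
    occurrence = run_counts / total_seconds

    outgoing = trans_counts.sum(axis=1)
    transition = np.full((k, k), np.nan)
    defined = outgoing > 0
    transition[defined] = trans_counts[defined] / outgoing[defined, None]
    return MicrostateParameters(coverage, duration_ms, occurrence, transition, defined)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def export_model(path, model: MicrostateModel, channel_labels) -> None:
    """Delimited K-map matrix with channel-label header and a metadata block."""
    import pandas as pd

    with open(path, "w") as fh:
        fh.write(f"# k={model.k} gev={model.gev:.6f} labels={','.join(model.labels or ())}\n")
        pd.DataFrame(model.maps, columns=list(channel_labels)).to_csv(fh, index=False)


def read_model(path) -> MicrostateModel:
    """Read a model written by :func:`export_model`."""
    import pandas as pd

    with open(path) as fh:
        meta = fh.readline().lstrip("# ").strip()
        fields = dict(item.split("=", 1) for item in meta.split())
        df = pd.read_csv(fh)
    labels = tuple(fields["labels"].split(",")) if fields.get("labels") else None
    return MicrostateModel(
        maps=df.to_numpy(float), gev=float(fields["gev"]), k=int(fields["k"]), labels=labels
    )


def segmentation_table(seg: LabeledSegmentation):
    """Per-epoch run-length table: epoch, state, start_ms, duration_ms."""
    import pandas as pd

    ms = 1000.0 / seg.sampling_rate_hz
    rows = [
        {"epoch": e, "state": s, "start_ms": start * ms, "duration_ms": length * ms}
        for e, segments in enumerate(seg.segments)
        for s, start, length in segments
    ]
    return pd.DataFrame(rows)


def parameters_table(subject_id: str, params: MicrostateParameters, state_labels=CANONICAL_LABELS):
    """Tidy per-subject rows: subject_id, state, coverage, duration_ms, occurrence_per_s."""
    import pandas as pd

    k = len(params.coverage)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "state": list(state_labels[:k]),
            "coverage": params.coverage,
            "duration_ms": params.duration_ms,
            "occurrence_per_s": params.occurrence_per_s,
        }
    )


def transitions_table(subject_id: str, params: MicrostateParameters, state_labels=CANONICAL_LABELS):
    """Long transition table: subject_id, from, to, probability (NaN if undefined)."""
    import pandas as pd

    k = params.transition.shape[0]
    rows = [
        {
            "subject_id": subject_id,
            "from": state_labels[i],
            "to": state_labels[j],
            "probability": params.transition[i, j],
        }
        for i in range(k)
        for j in range(k)
        if i != j
    ]
    return pd.DataFrame(rows)
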