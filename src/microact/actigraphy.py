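"""Wrist-actigraphy metrics for bilateral spontaneous arm movement.

Works on paired per-minute activity-count series from the affected and
unaffected arm.  Three summary metrics are computed, each over the whole
recording or restricted to a configurable day/night window:

* **ULAR** (upper limb activity ratio): total affected-arm counts divided by
  total unaffected-arm counts, in percent.
* **coordination index r**: Pearson correlation between the two per-minute
  count series.
* **moderate-activity minutes**: number of minutes with counts strictly
  above a threshold (default 500 counts/min), per arm.

Undefined quantities (zero unaffected activity, zero variance) are reported
as NaN, never silently coerced to 0 or infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import time as dtime
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_DAY_START = dtime(6, 0)
DEFAULT_NIGHT_START = dtime(22, 0)
DEFAULT_MODERATE_THRESHOLD = 500.0


def split_day_night(
    timestamps: pd.DatetimeIndex,
    day_start: dtime = DEFAULT_DAY_START,
    night_start: dtime = DEFAULT_NIGHT_START,
) -> np.ndarray:
    """Boolean day mask: True for minutes in [day_start, night_start).

    Handles wrap-around windows (e.g. day_start 22:00 / night_start 06:00
    marks the overnight block as "day", swapping the masks).
    """
    if day_start == night_start:
        raise ValueError("day_start and night_start must differ")
    tod = np.array([t.time() for t in timestamps])
    if day_start < night_start:
        return np.array([(day_start <= t) and (t < night_start) for t in tod])
    return np.array([(t >= day_start) or (t < night_start) for t in tod])


@dataclass
class ActigraphyPair:
    """Aligned per-minute count series for the affected and unaffected arm."""

    timestamps: pd.DatetimeIndex
    affected_counts: np.ndarray
    unaffected_counts: np.ndarray
    day_start: dtime = DEFAULT_DAY_START
    night_start: dtime = DEFAULT_NIGHT_START
    day_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.affected_counts = np.asarray(self.affected_counts, dtype=float)
        self.unaffected_counts = np.asarray(self.unaffected_counts, dtype=float)
        n = len(self.timestamps)
        if len(self.affected_counts) != n or len(self.unaffected_counts) != n:
            raise ValueError("count series must match timestamp length")
        if n >= 2:
            steps = np.diff(self.timestamps.asi8) / 1e9
            if not np.allclose(steps, 60.0):
                raise ValueError("timestamps must advance in strict 1-minute steps")
        if np.any(self.affected_counts < 0) or np.any(self.unaffected_counts < 0):
            raise ValueError("activity counts must be nonnegative")
        if self.day_mask is None:
            self.day_mask = split_day_night(self.timestamps, self.day_start, self.night_start)

    def window_mask(self, window: str) -> np.ndarray:
        if window == "all":
            return np.ones(len(self.timestamps), dtype=bool)
        if window == "day":
            return np.asarray(self.day_mask, dtype=bool)
        if window == "night":
            return ~np.asarray(self.day_mask, dtype=bool)
        raise ValueError(f"unknown window {window!r}; expected all|day|night")


def compute_ular(pair: ActigraphyPair, window: str = "all") -> float:
    """Upper limb activity ratio in percent over the given window.

    ULAR = sum(affected counts) / sum(unaffected counts) * 100.
    Returns NaN when the unaffected arm shows no activity in the window
    (the ratio is undefined there).
    """
    m = pair.window_mask(window)
    denom = pair.unaffected_counts[m].sum()
    if denom <= 0:
        return float("nan")
    return float(pair.affected_counts[m].sum() / denom * 100.0)


def compute_coordination_r(pair: ActigraphyPair, window: str = "all") -> float:
    """Pearson correlation between the two count series within the window.

    NaN when fewer than 3 minutes fall in the window or either series is
    constant there (correlation undefined).
    """
    m = pair.window_mask(window)
    x = pair.affected_counts[m]
    y = pair.unaffected_counts[m]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def moderate_activity_minutes(
    pair: ActigraphyPair,
    arm: str = "affected",
    threshold: float = DEFAULT_MODERATE_THRESHOLD,
    window: str = "all",
) -> int:
    """Minutes with counts strictly above the moderate-activity threshold."""
    if arm == "affected":
        series = pair.affected_counts
    elif arm == "unaffected":
        series = pair.unaffected_counts
    else:
        raise ValueError(f"unknown arm {arm!r}; expected affected|unaffected")
    m = pair.window_mask(window)
    return int(np.sum(series[m] > threshold))


def metrics_row(
    pair: ActigraphyPair, threshold: float = DEFAULT_MODERATE_THRESHOLD
) -> dict[str, float]:
    """Per-subject metric row: ULAR and r per window, moderate minutes per arm."""
    row: dict[str, float] = {}
    for window in ("all", "day", "night"):
        row[f"ular_{window}"] = compute_ular(pair, window)
        row[f"r_{window}"] = compute_coordination_r(pair, window)
    row["moderate_minutes_affected"] = moderate_activity_minutes(pair, "affected", threshold)
    row["moderate_minutes_unaffected"] = moderate_activity_minutes(pair, "unaffected", threshold)
    return row


def write_actigraphy(path: str | Path, pair: ActigraphyPair) -> Path:
    """Write the pair as a delimited table: timestamp, left, right columns.

    The affected arm is stored under ``affected_counts``/``unaffected_counts``
    directly; side mapping to left/right happens at load time via the subject
    sidecar (see :func:`load_actigraphy`).
    """
    df = pd.DataFrame(
        {
            "timestamp": pair.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "affected_counts": pair.affected_counts,
            "unaffected_counts": pair.unaffected_counts,
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def load_actigraphy(
    path: str | Path,
    affected_side: str | None = None,
    day_start: dtime = DEFAULT_DAY_START,
    night_start: dtime = DEFAULT_NIGHT_START,
) -> ActigraphyPair:
    """Read a delimited actigraphy table.

    Accepts either ``affected_counts``/``unaffected_counts`` columns or raw
    ``left_counts``/``right_counts`` columns plus ``affected_side``
    ("left"|"right") to resolve which wrist is the paretic one.
    """
    df = pd.read_csv(path)
    ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
    if {"affected_counts", "unaffected_counts"} <= set(df.columns):
        aff = df["affected_counts"].to_numpy(float)
        unaff = df["unaffected_counts"].to_numpy(float)
    elif {"left_counts", "right_counts"} <= set(df.columns):
        if affected_side not in ("left", "right"):
            raise ValueError("affected_side ('left'|'right') required for left/right tables")
        aff = df[f"{affected_side}_counts"].to_numpy(float)
        other = "right" if affected_side == "left" else "left"
        unaff = df[f"{other}_counts"].to_numpy(float)
    else:
        raise ValueError("table needs affected/unaffected or left/right count columns")
    return ActigraphyPair(ts, aff, unaff, day_start=day_start, night_start=night_start)
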