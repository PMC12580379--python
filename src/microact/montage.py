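"""Standard 10-20 electrode montage on an idealized unit sphere.

The 19-channel clinical montage (Fp1 ... O2, Cz; legacy temporal names
T3/T4/T5/T6) is resolved through MNE's built-in standard 10-20 electrode
positions, re-centered by a least-squares sphere fit and projected onto the
unit sphere.  Head frame: +x right, +y anterior, +z superior.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

#: The 19 scalp channels of the clinical 10-20 montage, in conventional order.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

DEFAULT_CHANNELS = CHANNELS_1020


def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit: returns (center, radius)."""
    A = np.c_[2.0 * points, np.ones(len(points))]
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


@lru_cache(maxsize=None)
def _standard_positions() -> dict[str, tuple[float, float, float]]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    return {name: tuple(map(float, xyz)) for name, xyz in pos.items()}


def get_montage(channels: tuple[str, ...] | list[str] = DEFAULT_CHANNELS) -> dict[str, np.ndarray]:
    """Unit-sphere 3-D coordinates for the requested 10-20 channel labels.

    Parameters
    ----------
    channels
        Channel labels; must resolve in the standard 10-20 position table.

    Returns
    -------
    dict mapping label -> unit-norm position (3,), ordered as requested.

    Raises
    ------
    KeyError
        If a label has no standard 10-20 coordinates (names the channel).
    """
    table = _standard_positions()
    missing = [ch for ch in channels if ch not in table]
    if missing:
        raise KeyError(f"no 10-20 montage coordinates for channel(s): {missing}")
    raw = np.array([table[ch] for ch in channels], dtype=float)
    # Center on the best-fit sphere of the full standard scalp set so a partial
    # montage still lands on the same idealized sphere.
    all_scalp = np.array([table[ch] for ch in CHANNELS_1020 if ch in table])
    center, _ = _fit_sphere(all_scalp)
    centered = raw - center
    unit = centered / np.linalg.norm(centered, axis=1, keepdims=True)
    return {ch: unit[i] for i, ch in enumerate(channels)}


def positions_array(montage: dict[str, np.ndarray], channels=None) -> np.ndarray:
    """Stack montage positions into an (n_channels, 3) array."""
    if channels is None:
        channels = list(montage)
    return np.array([montage[ch] for ch in channels], dtype=float)


def cosine_distances(pos: np.ndarray) -> np.ndarray:
    """Pairwise great-circle (angular) distances in radians between unit positions."""
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    return np.arccos(cosang)
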