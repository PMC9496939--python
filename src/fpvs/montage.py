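"""BioSemi 64-channel montage helpers and region-of-interest definitions.

Electrode coordinates come from MNE's standard ``biosemi64`` montage and are
projected onto the unit sphere, which is all the pipeline needs: nearest-
neighbour lookups for channel interpolation and smooth topography maps for
the simulator.
"""
from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

#: Regions of interest, fixed electrode sets.
ROIS: dict[str, tuple[str, ...]] = {
    "LOT": ("P7", "P9", "PO7"),
    "MO": ("Iz", "Oz", "O1", "O2"),
    "ROT": ("P8", "P10", "PO8"),
}

#: External (ocular) channels: EXG1/EXG2 at the outer canthi (horizontal
#: eye movements), EXG3 above and EXG4 below the right eye (vertical).
OCULAR: tuple[str, ...] = ("EXG1", "EXG2", "EXG3", "EXG4")

#: Vertical ocular pair used for blink detection (above minus below the eye).
VEOG_PAIR: tuple[str, str] = ("EXG3", "EXG4")


@lru_cache(maxsize=1)
def scalp_channels() -> tuple[str, ...]:
    """The 64 scalp electrode labels of the BioSemi 64 layout."""
    import mne

    mont = mne.channels.make_standard_montage("biosemi64")
    return tuple(mont.ch_names)


def all_channels() -> tuple[str, ...]:
    """Scalp channels followed by the four ocular channels."""
    return scalp_channels() + OCULAR


@lru_cache(maxsize=1)
def unit_sphere_positions() -> dict[str, np.ndarray]:
    """Map scalp label -> 3D position normalized to the unit sphere."""
    import mne

    mont = mne.channels.make_standard_montage("biosemi64")
    pos = mont.get_positions()["ch_pos"]
    out: dict[str, np.ndarray] = {}
    for name in mont.ch_names:
        p = np.asarray(pos[name], dtype=float)
        out[name] = p / np.linalg.norm(p)
    return out


def roi_centroid(roi: str) -> np.ndarray:
    """Unit-sphere centroid of an ROI's electrodes."""
    pos = unit_sphere_positions()
    c = np.mean([pos[ch] for ch in ROIS[roi]], axis=0)
    return c / np.linalg.norm(c)


def nearest_neighbors(
    label: str, k: int = 3, exclude: tuple[str, ...] = ()
) -> list[tuple[str, float]]:
    """The ``k`` spatially nearest good scalp electrodes to ``label``.

    Returns (label, euclidean distance) pairs sorted by distance; electrodes
    in ``exclude`` (e.g. other bad channels) and the target itself are not
    candidates.
    """
    pos = unit_sphere_positions()
    if label not in pos:
        raise ValueError(f"unknown scalp electrode {label!r}")
    target = pos[label]
    cands = [
        (ch, float(np.linalg.norm(pos[ch] - target)))
        for ch in scalp_channels()
        if ch != label and ch not in exclude
    ]
    cands.sort(key=lambda t: t[1])
    return cands[:k]


def interpolation_cap(n_scalp: int = 64, fraction: float = 0.05) -> int:
    """Maximum number of interpolatable channels: floor(fraction * n)."""
    return math.floor(fraction * n_scalp)
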