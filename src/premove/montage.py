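"""Electrode montage: the 30-channel 10-20 layout, 2-D head geometry, area partition.

Positions are an azimuthal-equidistant projection of the standard 10-20
spherical coordinates onto the plane (vertex at the origin, radius 1 at the
equatorial ring, nose toward +y). They are frozen as constants so the
synthetic forward model needs no I/O or external montage lookup.
"""

from __future__ import annotations

import numpy as np

#: Acquisition order of the 30 recorded electrodes; A2 is the reference.
CHANNELS_30: tuple[str, ...] = (
    "FP1", "FP2", "AF3", "AF4", "F7", "F8", "F3", "FZ", "F4",
    "FC5", "FC6", "T7", "T8", "C3", "CZ", "C4", "CP5", "CP6",
    "P7", "P8", "P3", "PZ", "P4", "PO7", "PO8", "PO3", "PO4",
    "O1", "O2", "A2",
)

REFERENCE_CHANNEL = "A2"

#: The 29 analysis channels (reference dropped).
ANALYSIS_CHANNELS: tuple[str, ...] = tuple(
    ch for ch in CHANNELS_30 if ch != REFERENCE_CHANNEL
)

#: 2-D projected positions (x: left-negative/right-positive, y: posterior-negative).
POSITIONS_2D: dict[str, tuple[float, float]] = {
    "FP1": (-0.3475, +0.9907),
    "FP2": (+0.3485, +0.9905),
    "AF3": (-0.3383, +0.7713),
    "AF4": (+0.3507, +0.7633),
    "F7": (-0.9311, +0.5628),
    "F3": (-0.4582, +0.4844),
    "FZ": (+0.0025, +0.4596),
    "F4": (+0.4716, +0.4940),
    "F8": (+0.9303, +0.5657),
    "FC5": (-0.7872, +0.1901),
    "FC6": (+0.7911, +0.1983),
    "T7": (-1.0503, -0.1999),
    "C3": (-0.5020, -0.0893),
    "CZ": (+0.0025, -0.0581),
    "C4": (+0.5146, -0.0836),
    "T8": (+1.0534, -0.1860),
    "CP5": (-0.6852, -0.4008),
    "CP6": (+0.6986, -0.3865),
    "P7": (-0.7129, -0.7230),
    "P3": (-0.3690, -0.5485),
    "PZ": (+0.0020, -0.4942),
    "P4": (+0.3827, -0.5400),
    "P8": (+0.7181, -0.7182),
    "PO7": (-0.4823, -0.8578),
    "PO3": (-0.2681, -0.7406),
    "PO4": (+0.2713, -0.7440),
    "PO8": (+0.4877, -0.8553),
    "O1": (-0.2408, -0.9207),
    "O2": (+0.2447, -0.9198),
    "A2": (+1.3577, -0.3958),
}

#: Partition of the 29 analysis channels into scalp areas. T7/T8 are grouped
#: with central for lack of a separate temporal category.
AREA_MAP: dict[str, str] = {}
for _ch in ("FP1", "FP2", "AF3", "AF4", "F7", "F3", "FZ", "F4", "F8"):
    AREA_MAP[_ch] = "frontal"
for _ch in ("FC5", "FC6", "T7", "C3", "CZ", "C4", "T8"):
    AREA_MAP[_ch] = "central"
for _ch in ("CP5", "CP6", "P7", "P3", "PZ", "P4", "P8"):
    AREA_MAP[_ch] = "parietal"
for _ch in ("PO7", "PO3", "PO4", "PO8", "O1", "O2"):
    AREA_MAP[_ch] = "occipital"
del _ch

AREAS: tuple[str, ...] = ("frontal", "central", "parietal", "occipital")


def normalize_label(label: str) -> str:
    """Map montage label spelling variants (Cz, FP1, fz, ...) to canonical form."""
    return label.strip().upper()


def positions_array(labels: list[str] | tuple[str, ...]) -> np.ndarray:
    """Stack 2-D positions for the given labels into an (n, 2) array.

    Raises
    ------
    KeyError
        If a label is not part of the montage.
    """
    out = np.empty((len(labels), 2))
    for i, lab in enumerate(labels):
        key = normalize_label(lab)
        if key not in POSITIONS_2D:
            raise KeyError(f"unknown electrode label: {lab!r}")
        out[i] = POSITIONS_2D[key]
    return out
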