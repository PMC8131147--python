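"""32-channel 10-20 electrode montage and 2-D scalp projection.

The channel set is the 32-electrode cap used by consumer-grade affect
studies (Fp1..O2 below).  Positions are classic 10-20 spherical angles
(polar angle from the vertex Cz, azimuth measured counter-clockwise from
the right ear, nose at +90 deg) mapped to the unit disc by azimuthal
equidistant projection, the standard flattening for scalp topography.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

# name -> (polar angle from vertex [deg], azimuth [deg], nose at +90)
_SPHERICAL: dict[str, tuple[float, float]] = {
    "Fp1": (90, 108), "AF3": (74, 113), "F3": (60, 129), "F7": (90, 144),
    "FC5": (69, 148), "FC1": (32, 124), "C3": (45, 180), "T7": (90, 180),
    "CP5": (69, -148), "CP1": (32, -124), "P3": (60, -129), "P7": (90, -144),
    "PO3": (74, -113), "O1": (90, -108), "Oz": (90, -90), "Pz": (45, -90),
    "Fp2": (90, 72), "AF4": (74, 67), "F4": (60, 51), "F8": (90, 36),
    "FC6": (69, 32), "FC2": (32, 56), "Cz": (0, 0), "C4": (45, 0),
    "T8": (90, 0), "CP6": (69, -32), "CP2": (32, -56), "P4": (60, -51),
    "P8": (90, -36), "PO4": (74, -67), "O2": (90, -72), "Fz": (45, 90),
}

CHANNEL_NAMES: tuple[str, ...] = tuple(_SPHERICAL)

# electrodes over prefrontal/frontal cortex, where beta activity rises
# with emotional activation
FRONTAL_CHANNELS: frozenset[str] = frozenset(
    {"Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz", "AF3", "AF4"}
)


def electrode_positions(names: tuple[str, ...] = CHANNEL_NAMES) -> np.ndarray:
    """(n, 2) unit-disc coordinates; x toward right ear, y toward nose."""
    pos = np.empty((len(names), 2))
    for i, name in enumerate(names):
        theta, phi = _SPHERICAL[name]
        r = theta / 115.0  # 90 deg ring lands at r=0.78, inside the disc
        pos[i] = r * np.cos(np.radians(phi)), r * np.sin(np.radians(phi))
    return pos


def frontal_mask(names: tuple[str, ...] = CHANNEL_NAMES) -> np.ndarray:
    return np.array([n in FRONTAL_CHANNELS for n in names])


def write_montage_csv(path: str | Path, names: tuple[str, ...] = CHANNEL_NAMES) -> None:
    pos = electrode_positions(names)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "x", "y"])
        for name, (x, y) in zip(names, pos):
            w.writerow([name, f"{x:.6f}", f"{y:.6f}"])
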