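"""Planar 10-20 electrode layout used by the synthetic generator.

Coordinates are 2-D projections of the standard 10-20 positions onto the
unit-radius head disc (nose up, left ear at negative x). Only relative
inter-channel distances matter downstream (Gaussian source topographies),
so a schematic equidistant grid of the standard rows is used.
"""

from __future__ import annotations

import numpy as np

# x: -1 (left ear) .. +1 (right ear); y: -1 (inion) .. +1 (nasion).
CHANNEL_POSITIONS: dict[str, tuple[float, float]] = {
    "FP1": (-0.25, 0.85),
    "FP2": (0.25, 0.85),
    "F7": (-0.65, 0.52),
    "F3": (-0.34, 0.45),
    "FZ": (0.0, 0.42),
    "F4": (0.34, 0.45),
    "F8": (0.65, 0.52),
    "FT7": (-0.74, 0.26),
    "FC3": (-0.38, 0.22),
    "FCZ": (0.0, 0.21),
    "FC4": (0.38, 0.22),
    "FT8": (0.74, 0.26),
    "T7": (-0.8, 0.0),
    "C3": (-0.4, 0.0),
    "CZ": (0.0, 0.0),
    "C4": (0.4, 0.0),
    "T8": (0.8, 0.0),
    "TP7": (-0.74, -0.26),
    "CP3": (-0.38, -0.22),
    "CPZ": (0.0, -0.21),
    "CP4": (0.38, -0.22),
    "TP8": (0.74, -0.26),
    "P7": (-0.65, -0.52),
    "P3": (-0.34, -0.45),
    "PZ": (0.0, -0.42),
    "P4": (0.34, -0.45),
    "P8": (0.65, -0.52),
}

#: 27-channel analysis montage (frontal-to-parietal order, conventional labels).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
)


def normalize_label(name: str) -> str:
    """Canonical upper-case form of a 10-20 label (``Cz`` -> ``CZ``)."""
    return name.strip().upper()


def channel_position(name: str) -> tuple[float, float]:
    key = normalize_label(name)
    try:
        return CHANNEL_POSITIONS[key]
    except KeyError:
        raise KeyError(f"No 10-20 position known for channel {name!r}") from None


def positions_array(channel_names) -> np.ndarray:
    """(n_channels, 2) array of planar positions for the given labels."""
    return np.array([channel_position(c) for c in channel_names], dtype=float)
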