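"""Electrode montages and 2-D scalp coordinates.

Two bundled layouts mirror the geometries of the common emotion-EEG
recording setups: a 32-channel Biosemi-style cap (128 Hz datasets) and a
62-channel 10-20/10-10 cap (200 Hz datasets).  3-D electrode positions come
from MNE-Python's standard montage resources and are flattened to 2-D with
an azimuthal-equidistant projection, the convention used for scalp
topographies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# Biosemi-32 channel order used by the 32-channel emotion datasets.
DEAP32_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

# 62-channel 10-10 layout of the 200 Hz five-emotion dataset.  CB1/CB2 are
# the cap's inferior-occipital electrodes; they sit at the PO9/PO10 sites of
# the extended 10-10 nomenclature.
SEEDV62_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "CB1", "O1", "Oz", "O2", "CB2",
)

_ALIASES = {"CB1": "PO9", "CB2": "PO10"}


@dataclass(frozen=True)
class Montage:
    """Ordered channel names plus 2-D scalp coordinates (unit-free)."""

    name: str
    channel_names: tuple[str, ...]
    coords: np.ndarray = field(repr=False)  # [n_channels, 2]

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.channel_names), 2):
            raise ValueError("coords must be [n_channels, 2]")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, channel: str) -> int:
        names = [c.lower() for c in self.channel_names]
        return names.index(channel.lower())


def _standard_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mont = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # pragma: no cover - newer naming
            mont = mne.channels.make_standard_montage("colin27_1005")
    pos = mont.get_positions()["ch_pos"]
    return {k.lower(): np.asarray(v, dtype=float) for k, v in pos.items()}


def _azimuthal_equidistant(xyz: np.ndarray) -> np.ndarray:
    """Project head-frame 3-D points to the plane: radius = polar angle."""
    x, y, z = xyz
    r = np.linalg.norm(xyz)
    if r == 0:
        return np.zeros(2)
    theta = np.arccos(np.clip(z / r, -1.0, 1.0))  # 0 at vertex
    phi = np.arctan2(y, x)
    return np.array([theta * np.cos(phi), theta * np.sin(phi)])


def get_montage(name_or_channels: str | list[str] | tuple[str, ...]) -> Montage:
    """Return a bundled montage by name ("deap32", "seedv62") or build one
    from an explicit channel list using standard 10-05 positions."""
    if isinstance(name_or_channels, str):
        key = name_or_channels.lower()
        if key == "deap32":
            channels, label = DEAP32_CHANNELS, "deap32"
        elif key == "seedv62":
            channels, label = SEEDV62_CHANNELS, "seedv62"
        else:
            raise KeyError(f"unknown montage {name_or_channels!r}")
    else:
        channels, label = tuple(name_or_channels), "custom"

    pos = _standard_positions()
    coords = np.empty((len(channels), 2))
    for i, ch in enumerate(channels):
        lookup = _ALIASES.get(ch.upper(), ch).lower()
        if lookup not in pos:
            raise KeyError(f"channel {ch!r} has no standard 10-05 position")
        coords[i] = _azimuthal_equidistant(pos[lookup])
    return Montage(label, channels, coords)
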