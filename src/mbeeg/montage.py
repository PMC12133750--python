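"""Electrode montages on the international 10-20 system.

A :class:`Montage` holds channel names and 3-D sensor positions projected
onto a unit sphere (a dimensionless spherical head model).  Positions are
taken from the standard 10-20 template bundled with :mod:`mne` and
normalised to unit norm, so inter-electrode Euclidean distances live in
[0, 2] "montage units".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Channel set used by the default 22-electrode montage.  Covers the motor
#: strip (C3/Cz/C4), the midline, and frontal/parietal/occipital sites.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2", "A1", "A2",
)


@dataclass(frozen=True)
class Montage:
    """Named electrodes with unit-sphere coordinates.

    Parameters
    ----------
    channel_names
        Unique 10-20 labels, one per electrode.
    positions
        Array of shape ``(n_channels, 3)``; each row has unit norm.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        pos = np.asarray(self.positions, dtype=float)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if pos.shape != (len(names), 3):
            raise ValueError(
                f"positions must be ({len(names)}, 3), got {pos.shape}"
            )
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must lie on the unit sphere (|r| = 1)")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        """Index of channel ``name``; raises ``KeyError`` if absent."""
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix, shape (C, C)."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(diff, axis=-1)


def standard_1020_montage(channels: tuple[str, ...] | list[str] | None = None) -> Montage:
    """Build a :class:`Montage` from the 10-20 template.

    Parameters
    ----------
    channels
        Channel names to include (default: the 22-channel set in
        :data:`DEFAULT_CHANNELS`).  Names must exist in the template.
    """
    import mne

    names = tuple(channels) if channels is not None else DEFAULT_CHANNELS
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        template = mne.channels.make_standard_montage("standard_1020")
    ch_pos = template.get_positions()["ch_pos"]
    missing = [n for n in names if n not in ch_pos]
    if missing:
        raise KeyError(f"channels not in the 10-20 template: {missing}")
    pos = np.array([ch_pos[n] for n in names], dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(channel_names=names, positions=pos)
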