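"""Canonical EEG frequency bands.

The five physiological bands used throughout the package: Delta 0.5-4 Hz,
Theta 4-8 Hz, Alpha 8-13 Hz, Beta 13-30 Hz, and Gamma from 30 Hz up to
min(100, 0.98 x Nyquist).  The Gamma ceiling adapts to the sampling rate:
after resampling to 128 Hz the Nyquist frequency is 64 Hz, so Gamma is
capped just below it.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"band {self.name}: need 0 < low < high, got [{self.low}, {self.high}]")

    def validate_for_fs(self, fs: float) -> None:
        if self.high > fs / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high} Hz exceeds Nyquist {fs / 2} Hz"
            )


def default_bands(fs: float) -> list[BandSpec]:
    """The five canonical bands, with Gamma capped below Nyquist for ``fs``."""
    gamma_high = min(100.0, 0.98 * fs / 2)
    if gamma_high <= 30.0:
        raise ValueError(f"fs={fs} Hz too low to represent a Gamma band above 30 Hz")
    return [
        BandSpec("Delta", 0.5, 4.0),
        BandSpec("Theta", 4.0, 8.0),
        BandSpec("Alpha", 8.0, 13.0),
        BandSpec("Beta", 13.0, 30.0),
        BandSpec("Gamma", 30.0, gamma_high),
    ]


def available_bands(fs: float) -> list[BandSpec]:
    """Canonical bands representable at ``fs``: upper edges are clipped
    to 0.98 x Nyquist and bands entirely above Nyquist are dropped.
    Unlike :func:`default_bands` this never raises for a low ``fs``."""
    ceiling = 0.98 * fs / 2
    out = []
    for name, low, high in [
        ("Delta", 0.5, 4.0),
        ("Theta", 4.0, 8.0),
        ("Alpha", 8.0, 13.0),
        ("Beta", 13.0, 30.0),
        ("Gamma", 30.0, 100.0),
    ]:
        if low >= ceiling:
            continue
        out.append(BandSpec(name, low, min(high, ceiling)))
    return out


def band_by_name(name: str, fs: float) -> BandSpec:
    for b in default_bands(fs):
        if b.name.lower() == name.lower():
            return b
    raise KeyError(f"unknown band {name!r}")
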