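"""Canonical neural frequency bands.

The five bands used throughout the pipeline follow standard MEG practice:
delta 1-4 Hz, theta 4-8 Hz, alpha 8-14 Hz, beta 14-30 Hz and low gamma
30-58 Hz (the gamma band stops short of 60 Hz line noise).  Band edges are
closed intervals, so an edge frequency shared by two adjacent bands (e.g.
4 Hz) contributes to both.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with closed edges ``[f_lo, f_hi]`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


CANONICAL_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 14.0),
    "beta": BandSpec("beta", 14.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 58.0),
}

BAND_NAMES: tuple[str, ...] = tuple(CANONICAL_BANDS)


def get_band(band: str | BandSpec) -> BandSpec:
    """Resolve a band name or pass a :class:`BandSpec` through."""
    if isinstance(band, BandSpec):
        return band
    try:
        return CANONICAL_BANDS[band]
    except KeyError:
        raise KeyError(
            f"unknown band {band!r}; canonical bands are {sorted(CANONICAL_BANDS)}"
        ) from None
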