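"""Frequency-band scheme and the phase/amplitude frequency grid.

The canonical scheme splits 0.5-45 Hz into eight bands (delta through
gamma).  Phase-amplitude coupling is evaluated on a grid whose rows are
the seven possible modulating (phase) bands -- gamma never acts as a
modulator -- and whose columns are 1-Hz-spaced amplitude bins.  An
amplitude bin is eligible for a phase band only when its centre lies
strictly above the band's upper edge, which yields 41, 37, 35, 32, 30,
26 and 16 eligible bins (217 cells in total) for the default scheme.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np


class Band(NamedTuple):
    name: str
    low: float
    high: float


#: Default band scheme: delta, theta, alpha1, alpha2, beta1, beta2, beta3, gamma.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 0.5, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha1", 8.0, 10.0),
    Band("alpha2", 10.0, 13.0),
    Band("beta1", 13.0, 15.0),
    Band("beta2", 15.0, 19.0),
    Band("beta3", 20.0, 29.0),
    Band("gamma", 30.0, 45.0),
)


def validate_scheme(bands: tuple[Band, ...]) -> tuple[Band, ...]:
    """Check ordering, positivity and name uniqueness of a band scheme."""
    names = [b.name for b in bands]
    if len(set(names)) != len(names):
        raise ValueError("band names must be unique")
    for b in bands:
        if not b.low < b.high:
            raise ValueError(f"band {b.name}: low must be < high")
    lows = [b.low for b in bands]
    if lows != sorted(lows):
        raise ValueError("bands must be in ascending frequency order")
    return tuple(bands)


def band_of(freq_hz: float, bands: tuple[Band, ...] = DEFAULT_BANDS) -> Band | None:
    """Band containing ``freq_hz``; edges belong to the lower band.

    Gaps between consecutive bands (e.g. 19-20 Hz in the default scheme)
    are assigned to the upper neighbour so every grid bin maps somewhere.
    """
    prev_high = 0.0
    for b in bands:
        if prev_high < freq_hz <= b.high:
            return b
        prev_high = b.high
    return None


@dataclass(frozen=True)
class FrequencyGrid:
    """Grid of (phase band, amplitude bin) PAC cells.

    Amplitude bins are integer centres ``amp_lo..amp_hi`` Hz; eligibility
    requires the centre to exceed the phase band's upper edge.
    """

    bands: tuple[Band, ...] = DEFAULT_BANDS
    amp_lo: int = 1
    amp_hi: int = 45

    def __post_init__(self):
        validate_scheme(self.bands)

    @property
    def phase_bands(self) -> tuple[Band, ...]:
        return self.bands[:-1]

    @property
    def amp_centers(self) -> np.ndarray:
        return np.arange(self.amp_lo, self.amp_hi + 1)

    def eligible_bins(self, band: Band) -> np.ndarray:
        c = self.amp_centers
        return c[c > band.high]

    @property
    def cells(self) -> list[tuple[Band, int]]:
        out = []
        for b in self.phase_bands:
            out.extend((b, int(c)) for c in self.eligible_bins(b))
        return out

    @property
    def n_cells(self) -> int:
        return sum(len(self.eligible_bins(b)) for b in self.phase_bands)

    def amp_half_width(self, band: Band) -> float:
        """Half-width of the amplitude-bin filter used for this phase row.

        The passband must be wide enough that (a) the modulation sidebands
        at ``bin +/- f_phase`` are captured for any modulator inside the
        band and (b) the envelope of the filtered carrier can fluctuate at
        the band's own frequencies.  ``max(1, band midpoint)`` satisfies
        both while staying as narrow as the grid's 1-Hz semantics allow.
        """
        return max(1.0, (band.low + band.high) / 2.0)
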