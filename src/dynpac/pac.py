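"""Phase-amplitude coupling for a single analysis window.

The coupling chain for one (phase band, amplitude bin) cell:

1. band-pass the phase-channel signal in the phase band; Hilbert phase
   gives ``phi_LF(t)``;
2. band-pass the amplitude-channel signal around the bin centre, take the
   Hilbert envelope ``A_HF(t)``;
3. band-pass that envelope in the phase band and take its Hilbert phase,
   ``phi_LF->HF(t)``, the phase at which the LF rhythm modulates the HF
   amplitude;
4. the wrapped difference ``dphi = phi_LF - phi_LF->HF`` enters the
   phase-locking value (PLV) or its imaginary part (iPLV).

iPLV discards zero-lag coupling and is the default coupling strength.
The comodulogram evaluates every eligible cell of a
:class:`~dynpac.bands.FrequencyGrid`; ``select_max`` returns the winning
cell subject to the power-separation criterion (the modulating band's
spectral peak must sit at least 1 Hz from the broadband spectral peak, so
that couplings driven by the dominant rhythm's power are excluded).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import DEFAULT_BANDS, Band, FrequencyGrid
from .preprocessing import bandpass

__all__ = [
    "AnalyticSignal", "analytic", "PhaseDifferenceSeries",
    "pac_phase_differences", "plv", "iplv", "Comodulogram", "comodulogram",
    "select_max", "power_separation_ok", "amp_filter_edges", "spectral_peak",
]


@dataclass
class AnalyticSignal:
    """Envelope and phase of the analytic extension of a real series."""

    amplitude: np.ndarray
    phase: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.amplitude * np.cos(self.phase)

    @property
    def phasor(self) -> np.ndarray:
        return np.exp(1j * self.phase)


def analytic(series: np.ndarray) -> AnalyticSignal:
    """Hilbert-transform analytic signal (envelope + instantaneous phase)."""
    x = np.asarray(series, float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("series must be 1-D with at least 8 samples")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    z = sps.hilbert(x)
    return AnalyticSignal(np.abs(z), np.angle(z))


@dataclass
class PhaseDifferenceSeries:
    """Wrapped phase differences entering PLV/iPLV."""

    delta_phi: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.delta_phi.size


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * phi))


def amp_filter_edges(amp_bin: int, phase_band: Band, rate_hz: float,
                     half_width: float | None = None) -> tuple[float, float]:
    """Pass-band of the amplitude-bin filter for a given phase row.

    Default half-width adapts to the phase band (``max(1, band
    midpoint)``) so the modulation sidebands at ``bin +/- f_phase`` are
    captured; the lower edge never descends into the phase band itself.
    """
    h = half_width if half_width is not None else max(
        1.0, (phase_band.low + phase_band.high) / 2.0)
    lo = max(amp_bin - h, phase_band.high)
    hi = min(amp_bin + h, rate_hz / 2 - 1.0)
    if lo >= hi:
        raise ValueError("degenerate amplitude filter band")
    return lo, hi


def pac_phase_differences(lf_series: np.ndarray, hf_series: np.ndarray,
                          phase_band: Band, amp_bin: int, rate_hz: float,
                          amp_half_width: float | None = None
                          ) -> PhaseDifferenceSeries:
    """Phase differences between the LF phase and the HF envelope phase."""
    lf = np.asarray(lf_series, float)
    hf = np.asarray(hf_series, float)
    if lf.shape != hf.shape:
        raise ValueError("windows must have equal length")
    phi_lf = analytic(bandpass(lf, phase_band.low, phase_band.high, rate_hz)).phase
    lo, hi = amp_filter_edges(amp_bin, phase_band, rate_hz, amp_half_width)
    env = analytic(bandpass(hf, lo, hi, rate_hz)).amplitude
    env_b = bandpass(env - env.mean(), phase_band.low, phase_band.high, rate_hz)
    phi_mod = analytic(env_b).phase
    return PhaseDifferenceSeries(wrap_phase(phi_lf - phi_mod))


def plv(dphi: PhaseDifferenceSeries | np.ndarray) -> float:
    """Phase-locking value: modulus of the mean unit phasor."""
    d = dphi.delta_phi if isinstance(dphi, PhaseDifferenceSeries) else np.asarray(dphi)
    if d.size < 1:
        raise ValueError("empty phase-difference series")
    return float(np.abs(np.exp(1j * d).mean()))


def iplv(dphi: PhaseDifferenceSeries | np.ndarray) -> float:
    """Imaginary PLV: |imaginary part| of the mean phasor (zero-lag blind)."""
    d = dphi.delta_phi if isinstance(dphi, PhaseDifferenceSeries) else np.asarray(dphi)
    if d.size < 1:
        raise ValueError("empty phase-difference series")
    return float(np.abs(np.exp(1j * d).mean().imag))


def spectral_peak(window: np.ndarray, rate_hz: float,
                  fmin: float = 0.5, fmax: float = 45.0) -> float:
    """Frequency of the Hann-periodogram maximum within [fmin, fmax]."""
    x = np.asarray(window, float)
    if not np.any(x):
        raise ValueError("all-zero window has no spectral peak")
    freqs, pxx = sps.periodogram(x, fs=rate_hz, window="hann")
    sel = (freqs >= fmin) & (freqs <= fmax)
    return float(freqs[sel][np.argmax(pxx[sel])])


def power_separation_ok(lf_window: np.ndarray, broadband_window: np.ndarray,
                        rate_hz: float, min_sep_hz: float = 1.0) -> bool:
    """True when the LF spectral peak is >= min_sep_hz from the broadband peak.

    Guards against 'couplings' whose modulating frequency is simply the
    dominant rhythm of the record.
    """
    lf_peak = spectral_peak(lf_window, rate_hz)
    bb_peak = spectral_peak(broadband_window, rate_hz)
    return bool(abs(lf_peak - bb_peak) >= min_sep_hz)


@dataclass
class Comodulogram:
    """iPLV (and optional PLV) over the (phase band, amplitude bin) grid.

    ``values[r, c]`` is NaN for ineligible cells.  ``power_ok`` marks
    rows/cells passing the power-separation criterion.
    """

    grid: FrequencyGrid
    values: np.ndarray            # (n_phase_bands, n_amp_bins)
    power_ok: np.ndarray          # same shape, bool
    plv_values: np.ndarray | None = None
    pair: tuple[int, int] | None = None
    window: int | None = None

    def cell_value(self, band: Band, amp_bin: int) -> float:
        r = [b.name for b in self.grid.phase_bands].index(band.name)
        c = int(amp_bin) - self.grid.amp_lo
        return float(self.values[r, c])


def comodulogram(window_i: np.ndarray, window_j: np.ndarray, rate_hz: float,
                 grid: FrequencyGrid | None = None,
                 amp_half_width: float | None = None,
                 compute_plv: bool = False,
                 power_criterion: bool = True) -> Comodulogram:
    """iPLV comodulogram between two windows (within-sensor when identical).

    Degenerate (zero-variance) windows yield zeros with ``power_ok`` False
    rather than an error so batch runs never abort.
    """
    grid = grid or FrequencyGrid()
    wi = np.asarray(window_i, float)
    wj = np.asarray(window_j, float)
    if wi.shape != wj.shape:
        raise ValueError("windows must have equal length")
    nb = len(grid.phase_bands)
    nc = grid.amp_hi - grid.amp_lo + 1
    vals = np.full((nb, nc), np.nan)
    pvals = np.full((nb, nc), np.nan) if compute_plv else None
    pok = np.zeros((nb, nc), bool)
    degenerate = wi.std() == 0 or wj.std() == 0
    for r, band in enumerate(grid.phase_bands):
        cols = grid.eligible_bins(band) - grid.amp_lo
        if degenerate:
            vals[r, cols] = 0.0
            if compute_plv:
                pvals[r, cols] = 0.0
            continue
        row_ok = True
        if power_criterion:
            lf = bandpass(wi, band.low, band.high, rate_hz)
            row_ok = power_separation_ok(lf, bandpass(wi, 0.5, 45.0, rate_hz),
                                         rate_hz)
        for c in grid.eligible_bins(band):
            d = pac_phase_differences(wi, wj, band, int(c), rate_hz,
                                      amp_half_width)
            col = int(c) - grid.amp_lo
            vals[r, col] = iplv(d)
            if compute_plv:
                pvals[r, col] = plv(d)
            pok[r, col] = row_ok
    if not power_criterion:
        pok = ~np.isnan(vals)
    return Comodulogram(grid, vals, pok, pvals)


def select_max(com: Comodulogram) -> tuple[Band, int, float] | None:
    """Highest-value cell passing the power mask; ties resolve toward the
    lowest phase band, then the lowest amplitude bin.  None if all masked."""
    cand = np.where(com.power_ok & ~np.isnan(com.values), com.values, -np.inf)
    if not np.isfinite(cand).any():
        return None
    r, c = np.unravel_index(np.argmax(cand), cand.shape)  # argmax -> first max
    band = com.grid.phase_bands[r]
    return band, int(c + com.grid.amp_lo), float(com.values[r, c])
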