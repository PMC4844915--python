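"""Sliding-window dynamic PAC graphs and their temporal-variability indices.

``build_tvpac`` is the workhorse: for every requested directed sensor
pair and every 2-s window (0.5-s steps) it evaluates the full
(phase band x amplitude bin) comodulogram, tests each cell against
cut-swap surrogates of the low-frequency phase series, corrects across
the cells with Benjamini-Hochberg, applies the power-separation
criterion, and stores the window's prominent mode (or none).

From the resulting time-varying mode series the module derives

* strength series -- network-summed prominent iPLV per window;
* transition rate (TR) -- fraction of consecutive-window opportunities
  at which the mode label changes, counted only between two windows that
  both carry a significant mode;
* dIER / wdIER -- per-window sums over pairs of (HF cycles / LF cycles),
  optionally weighted by the mode's iPLV;
* PD matrix -- empirical probability distribution of prominent band-pair
  modes (the coupling "repertoire");
* mean + 2 SD topographic thresholding and sample entropy of the index
  time series.

Implementation notes.  Phase/envelope series are filtered and
Hilbert-transformed once over the full record, then sliced per window;
windows inside ``pad_s`` of the record edges are excluded (filter and
Hilbert transients there masquerade as coupling).  Surrogates shift the
LF phase series circularly over the trimmed interior by at least one
window length -- the full-record realisation of the cut-swap.  Window
statistics are computed from phasor products decimated 8-fold (the
products of same-band phasors are band-limited well below the decimated
Nyquist, so decimated means agree with exact means to about a percent);
surrogate counting runs as blocked BLAS contractions shared across the
pairs that reuse a phase channel.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import signal as sps

from .bands import DEFAULT_BANDS, Band, FrequencyGrid, band_of
from .pac import amp_filter_edges
from .preprocessing import orthogonalize_pair
from .recording import Recording
from .surrogates import SurrogateConfig

__all__ = [
    "WindowingSpec", "make_windows", "ProminentMode", "TVPACResult",
    "build_tvpac", "mode_label", "strength_series", "transition_rate",
    "tr_matrix", "dier", "wdier", "dier_series", "wdier_series",
    "PDMatrix", "pd_pac", "threshold_topography", "sample_entropy",
    "EntropyConfig",
    "choose_delay", "choose_dimension",
]


@dataclass(frozen=True)
class WindowingSpec:
    """Sliding-window geometry: 2-s windows advanced in 0.5-s steps by
    default (two cycles of the slowest modulating band per window)."""

    width_s: float = 2.0
    step_s: float = 0.5

    def __post_init__(self):
        if not 0 < self.step_s <= self.width_s:
            raise ValueError("require 0 < step_s <= width_s")


def make_windows(duration_s: float, spec: WindowingSpec = WindowingSpec(),
                 rate_hz: float = 256.0) -> list[tuple[int, int]]:
    """Half-open sample windows covering the duration.

    Count equals ``floor((duration - width) / step) + 1``.
    """
    if duration_s < spec.width_s:
        raise ValueError("duration shorter than one window")
    T = int(round(spec.width_s * rate_hz))
    step = int(round(spec.step_s * rate_hz))
    n = int(round(duration_s * rate_hz))
    starts = np.arange(0, n - T + 1, step)
    return [(int(s), int(s + T)) for s in starts]


class ProminentMode(NamedTuple):
    """Winning coupling mode of one pair in one window."""

    phase_band: str
    amp_hz: int
    strength: float      # iPLV of the winning cell
    lf_cycles: int       # complete LF cycles observed in the window


def mode_label(mode: ProminentMode | None,
               bands: tuple[Band, ...] = DEFAULT_BANDS
               ) -> tuple[str, str] | None:
    """(phase band, amplitude band) label of a mode; None passes through."""
    if mode is None:
        return None
    ab = band_of(mode.amp_hz, bands)
    return (mode.phase_band, ab.name if ab else "?")


@dataclass
class TVPACResult:
    """Time-varying PAC graph: per-pair prominent-mode series."""

    modes: dict[tuple[int, int], list[ProminentMode | None]]
    window_times: np.ndarray            # window start times, seconds
    windowing: WindowingSpec
    grid: FrequencyGrid
    rate_hz: float
    values: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    cells: list[tuple[str, int]] = field(default_factory=list)
    sig_counts: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.window_times)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(self.modes)

    def labels(self, pair: tuple[int, int]) -> list[tuple[str, str] | None]:
        return [mode_label(m, self.grid.bands) for m in self.modes[pair]]


class _SpectralFilters:
    """Zero-phase Butterworth filtering + analytic signal in one FFT pass.

    Forward-backward filtering has magnitude response |H|^2 and zero
    phase, so the band-limited analytic signal equals the inverse FFT of
    the one-sided spectrum weighted by |H|^2.  Circular edge effects stay
    within the filter ring-down and are removed by the engine's edge
    padding.  Responses are cached per (low, high) band.
    """

    def __init__(self, n: int, rate_hz: float, order: int = 3):
        self.n = n
        self.rate_hz = rate_hz
        self.order = order
        self.freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
        self._gain: dict[tuple[float, float], np.ndarray] = {}

    def gain(self, low: float, high: float) -> np.ndarray:
        key = (low, high)
        if key not in self._gain:
            sos = sps.butter(self.order, [low, high], btype="bandpass",
                             fs=self.rate_hz, output="sos")
            _, h = sps.sosfreqz(sos, worN=self.freqs, fs=self.rate_hz)
            self._gain[key] = np.abs(h) ** 2
        return self._gain[key]

    def analytic(self, x_rfft: np.ndarray, low: float, high: float
                 ) -> np.ndarray:
        spec = np.zeros(self.n, complex)
        g = self.gain(low, high)
        spec[:self.freqs.size] = 2.0 * x_rfft * g
        spec[0] *= 0.5
        if self.n % 2 == 0:
            spec[self.n // 2] *= 0.5
        return np.fft.ifft(spec)

    def bandpass_real(self, x_rfft: np.ndarray, low: float, high: float
                      ) -> np.ndarray:
        return np.fft.irfft(x_rfft * self.gain(low, high), self.n)


def _phase_channel_features(x, rate_hz, grid, pad, starts, T):
    """Per phase band: unit phasor, unwrapped phase, periodogram peak per
    window; plus the broadband peak per window.  All on the trimmed interior."""
    n = x.size
    u, phi_un, lf_peak = {}, {}, {}
    win = np.hanning(T)
    freqs = np.fft.rfftfreq(T, 1.0 / rate_hz)
    sel = (freqs >= 0.5) & (freqs <= 45.0)
    idxT = starts[:, None] + np.arange(T)[None, :]
    sf = _SpectralFilters(n, rate_hz)
    xf_r = np.fft.rfft(x)
    bb = sf.bandpass_real(xf_r, 0.5, 45.0)[pad:n - pad]
    pxx = np.abs(np.fft.rfft(bb[idxT] * win, axis=1)) ** 2
    bb_peak = freqs[sel][np.argmax(pxx[:, sel], axis=1)]
    for b in grid.phase_bands:
        z = sf.analytic(xf_r, b.low, b.high)
        zi = z[pad:n - pad]
        u[b.name] = (zi / np.maximum(np.abs(zi), 1e-12)).astype(np.complex64)
        phi_un[b.name] = np.unwrap(np.angle(zi))
        xfi = zi.real
        pxx = np.abs(np.fft.rfft(xfi[idxT] * win, axis=1)) ** 2
        lf_peak[b.name] = freqs[sel][np.argmax(pxx[:, sel], axis=1)]
    return u, phi_un, lf_peak, bb_peak


def _envelope_phasors(x, rate_hz, grid, pad, amp_half_width, x_ref=None):
    """Per (phase band, amplitude bin): unit phasor of the band-filtered
    Hilbert envelope.  When ``x_ref`` is given the bin-filtered analytic
    signal is first orthogonalized against the reference channel's."""
    n = x.size
    sf = _SpectralFilters(n, rate_hz)
    xf_r = np.fft.rfft(x)
    ref_r = np.fft.rfft(x_ref) if x_ref is not None else None
    out = {}
    for b in grid.phase_bands:
        rows = []
        for c in grid.eligible_bins(b):
            lo, hi = amp_filter_edges(int(c), b, rate_hz, amp_half_width)
            z = sf.analytic(xf_r, lo, hi)
            if ref_r is not None:
                z = orthogonalize_pair(sf.analytic(ref_r, lo, hi), z)
            env = np.abs(z)
            ze = sf.analytic(np.fft.rfft(env - env.mean()),
                             b.low, b.high)[pad:n - pad]
            rows.append((ze / np.maximum(np.abs(ze), 1e-12)).astype(np.complex64))
        out[b.name] = np.array(rows)
    return out


def _windowed_iplv(prod_dec, w_dec, Td, scale):
    """|Im| of windowed sums of (decimated) phasor products.

    prod_dec : (..., nd) complex; returns (..., nw) float.
    """
    cs = np.concatenate(
        [np.zeros(prod_dec.shape[:-1] + (1,), prod_dec.dtype),
         np.cumsum(prod_dec, axis=-1)], axis=-1)
    s = cs[..., w_dec + Td] - cs[..., w_dec]
    return np.abs(s.imag) * scale


def _windowed_abs_sums(im_prod, w_dec, Td, scale):
    """|windowed sums| of the (real) imaginary parts of phasor products."""
    cs = np.concatenate(
        [np.zeros(im_prod.shape[:-1] + (1,), np.float32),
         np.cumsum(im_prod, axis=-1, dtype=np.float32)], axis=-1)
    return np.abs(cs[..., w_dec + Td] - cs[..., w_dec]) * scale


def _block_im_sums(vr, vi, ur, ui, bs):
    """Block-summed Im(u * conj(v)) as a fused BLAS contraction.

    vr/vi : (nbins, nd); ur/ui : (noffs, nd); returns (nbins, noffs, nblk)
    with nblk = nd // bs.
    """
    nbins, nd = vr.shape
    noffs = ur.shape[0]
    nblk = nd // bs
    v3r = vr[:, :nblk * bs].reshape(nbins, nblk, bs)
    v3i = vi[:, :nblk * bs].reshape(nbins, nblk, bs)
    u3r = ur[:, :nblk * bs].reshape(noffs, nblk, bs)
    u3i = ui[:, :nblk * bs].reshape(noffs, nblk, bs)
    return (np.einsum("nbk,obk->nob", v3r, u3i, optimize=True)
            - np.einsum("nbk,obk->nob", v3i, u3r, optimize=True))


def _bh_mask_matrix(pvals, q):
    """Vectorized Benjamini-Hochberg step-up per column of (m, nw)."""
    m, nw = pvals.shape
    order = np.argsort(pvals, axis=0, kind="stable")
    ps = np.take_along_axis(pvals, order, axis=0)
    thr = (q * np.arange(1, m + 1) / m)[:, None]
    passed = ps <= thr
    kmax = np.where(passed.any(axis=0),
                    m - 1 - np.argmax(passed[::-1], axis=0), -1)
    cutoff = np.where(kmax >= 0,
                      ps[np.clip(kmax, 0, m - 1), np.arange(nw)], -1.0)
    return pvals <= cutoff[None, :]


def build_tvpac(rec: Recording,
                grid: FrequencyGrid | None = None,
                windowing: WindowingSpec = WindowingSpec(),
                surrogate: SurrogateConfig = SurrogateConfig(),
                pairs: list[tuple[int, int]] | None = None,
                pad_s: float = 2.0,
                orthogonalize: bool = False,
                amp_half_width: float | None = None,
                mode_selection: str = "band_sum",
                min_sig_bins: int = 3,
                decimate: int = 8,
                chunk: int = 100) -> TVPACResult:
    """Prominent-mode series for every requested directed pair.

    Parameters
    ----------
    pairs : list of (phase channel, amplitude channel); default all ordered
        pairs including the within-sensor diagonal.
    pad_s : seconds excluded at both record edges.
    orthogonalize : remove the zero-lag in-phase component of the amplitude
        channel relative to the phase channel per amplitude bin (leakage
        correction; slower, default off for leakage-free synthetic data).
    mode_selection : "band_sum" (default) integrates significant cells
        within each of the 28 (phase band, amplitude band) pairs -- the
        window's mode is the band pair with the highest summed iPLV over
        its significant bins, and the mode's 1-Hz bin is the strongest
        significant bin inside it.  "band_mean" averages each pair's bins
        instead; "bin_max" picks the single strongest significant bin
        outright.  Band integration suppresses isolated chance-floor bins
        in the narrow phase-band rows, whose few-DOF nulls otherwise
        out-value genuine couplings.
    min_sig_bins : a band pair qualifies as a window's mode only with at
        least this many significant bins (band_sum/band_mean modes).  A
        genuine band-level coupling excites the whole sideband-sharing bin
        plateau, whereas an isolated single-bin exceedance is the
        signature of a finite-resolution surrogate floor.
    decimate : decimation factor for phasor-product window sums (the
        products of same-band phasors are band-limited below fs/(2*8) for
        every band of the default scheme).
    chunk : surrogate offsets processed per vectorized block.
    """
    grid = grid or FrequencyGrid()
    fs = rec.rate_hz
    T = int(round(windowing.width_s * fs))
    pad = int(round(pad_s * fs))
    n = rec.n_samples
    ni = n - 2 * pad
    if ni < 2 * T:
        raise ValueError("recording too short for the requested windows/padding")
    step = int(round(windowing.step_s * fs))
    starts = np.arange(0, ni - T + 1, step)
    nw = len(starts)
    D = max(int(decimate), 1)
    s_dec = np.arange(0, ni, D)
    nd = s_dec.size
    Td = T // D
    w_dec = starts // D
    scale = D / T
    rng = np.random.default_rng(surrogate.seed)
    lo_off = T
    hi_off = ni - T
    pool = np.arange(lo_off, hi_off)
    n_surr = min(surrogate.n_surrogates, pool.size)
    offs = rng.choice(pool, size=n_surr, replace=False)

    if pairs is None:
        nc = rec.n_channels
        pairs = [(i, j) for i in range(nc) for j in range(nc)]

    # per-channel precomputation
    phase_feats = {}
    env_feats = {}
    for ch in sorted({p[0] for p in pairs}):
        phase_feats[ch] = _phase_channel_features(
            rec.channel(ch), fs, grid, pad, starts, T)
    if not orthogonalize:
        for ch in sorted({p[1] for p in pairs}):
            env_feats[ch] = _envelope_phasors(
                rec.channel(ch), fs, grid, pad, amp_half_width)

    cells = [(b.name, int(c)) for b in grid.phase_bands
             for c in grid.eligible_bins(b)]
    m_cells = len(cells)
    modes: dict[tuple[int, int], list[ProminentMode | None]] = {}
    values: dict[tuple[int, int], np.ndarray] = {}
    sig_counts: dict[tuple[int, int], np.ndarray] = {}

    # circular shifted LF phasors are shared across pairs with the same
    # phase channel and band; cache their decimated real/imag parts
    shift_cache: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}

    def shifted(ch, band_name):
        key = (ch, band_name)
        if key not in shift_cache:
            u = phase_feats[ch][0][band_name]
            idx = (s_dec[None, :] + offs[:, None]) % ni
            uc = u[idx]
            shift_cache[key] = (uc.real.astype(np.float32),
                                uc.imag.astype(np.float32))
        return shift_cache[key]

    for (i, j) in pairs:
        u_i, phi_i, lf_peak_i, bb_peak_i = phase_feats[i]
        if orthogonalize and i != j:
            env_j = _envelope_phasors(rec.channel(j), fs, grid, pad,
                                      amp_half_width, x_ref=rec.channel(i))
        else:
            if j not in env_feats:
                env_feats[j] = _envelope_phasors(
                    rec.channel(j), fs, grid, pad, amp_half_width)
            env_j = env_feats[j]
        obs = np.zeros((m_cells, nw), np.float32)
        pval = np.ones((m_cells, nw), np.float32)
        row = 0
        step_dec = step // D if step % D == 0 else 0
        aligned = step_dec > 0 and step_dec <= Td and Td % step_dec == 0
        for b in grid.phase_bands:
            V = env_j[b.name]                       # (nbins, ni) complex64
            if V.size == 0:
                continue
            nbins = V.shape[0]
            u = u_i[b.name]
            # Im(u * conj(v)) = u_im * v_re - u_re * v_im
            vr = V[:, s_dec].real.astype(np.float32)
            vi = V[:, s_dec].imag.astype(np.float32)
            ud = u[s_dec]
            udr = ud.real.astype(np.float32)[None, :]
            udi = ud.imag.astype(np.float32)[None, :]
            ur_s, ui_s = shifted(i, b.name)         # (n_surr, nd)
            if aligned:
                bs = step_dec
                nblkw = Td // bs
                wb = w_dec // bs

                def window_vals(ur_, ui_):
                    blk = _block_im_sums(vr, vi, ur_, ui_, bs)
                    cs = np.concatenate(
                        [np.zeros(blk.shape[:-1] + (1,), np.float32),
                         np.cumsum(blk, axis=-1, dtype=np.float32)], axis=-1)
                    return np.abs(cs[..., wb + nblkw] - cs[..., wb]) * scale

                obs_b = window_vals(udr, udi)[:, 0, :]
                vals = window_vals(ur_s, ui_s)      # (nbins, n_surr, nw)
                counts = (vals >= obs_b[:, None, :]).sum(axis=1)
            else:
                im0 = udi * vr - udr * vi
                obs_b = _windowed_abs_sums(im0, w_dec, Td, scale)
                counts = np.zeros((nbins, nw), np.int32)
                for c0 in range(0, n_surr, chunk):
                    sl = slice(c0, min(c0 + chunk, n_surr))
                    im_q = (ui_s[None, sl, :] * vr[:, None, :]
                            - ur_s[None, sl, :] * vi[:, None, :])
                    vals = _windowed_abs_sums(im_q, w_dec, Td, scale)
                    counts += (vals >= obs_b[:, None, :]).sum(axis=1)
            obs[row:row + nbins] = obs_b
            pval[row:row + nbins] = counts / n_surr
            row += nbins
        if surrogate.p_convention == "add_one":
            # conservative floor: one pseudo-exceedance per cell
            pval = (pval * n_surr + 1) / (n_surr + 1)

        # per-window BH + power mask + argmax
        band_rows = {}
        r0 = 0
        for b in grid.phase_bands:
            nbins = len(grid.eligible_bins(b))
            band_rows[b.name] = (r0, r0 + nbins)
            r0 += nbins
        power_row = np.zeros((m_cells, nw), bool)
        for b in grid.phase_bands:
            r0, r1 = band_rows[b.name]
            ok = np.abs(lf_peak_i[b.name] - bb_peak_i) >= 1.0
            power_row[r0:r1] = ok[None, :]
        # cell index -> (phase band, amplitude band) group
        group_of = {}
        for ci, (bn, c) in enumerate(cells):
            ab = band_of(c, grid.bands)
            group_of.setdefault((bn, ab.name if ab else "?"), []).append(ci)
        groups = {g: np.array(ix) for g, ix in group_of.items()}

        sig_all = _bh_mask_matrix(pval.astype(float), surrogate.q)
        mode_list: list[ProminentMode | None] = []
        for w in range(nw):
            cand = sig_all[:, w] & power_row[:, w]
            if not cand.any():
                mode_list.append(None)
                continue
            if mode_selection in ("band_sum", "band_mean"):
                best, best_val = None, -np.inf
                for g, ix in groups.items():
                    good = ix[cand[ix]]
                    if good.size < max(min_sig_bins, 1):
                        continue
                    if mode_selection == "band_sum":
                        v = float(obs[good, w].sum())
                    else:
                        v = float(obs[ix, w].mean())
                    if v > best_val:
                        best, best_val = g, v
                if best is None:
                    mode_list.append(None)
                    continue
                ix = groups[best]
                ix = ix[cand[ix]]
                ci = int(ix[np.argmax(obs[ix, w])])
            elif mode_selection == "bin_max":
                vals_w = np.where(cand, obs[:, w], -np.inf)
                ci = int(np.argmax(vals_w))
            else:
                raise ValueError(
                    "mode_selection must be 'band_sum', 'band_mean' or 'bin_max'")
            bn, c = cells[ci]
            span = phi_i[bn][starts[w] + T - 1] - phi_i[bn][starts[w]]
            cyc = max(int(span // (2 * np.pi)), 0)
            mode_list.append(ProminentMode(bn, c, float(obs[ci, w]), cyc))
        modes[(i, j)] = mode_list
        values[(i, j)] = obs
        sig_counts[(i, j)] = sig_all.sum(axis=0).astype(int)
    times = (starts + pad) / fs
    return TVPACResult(modes, times, windowing, grid, fs, values, cells,
                       sig_counts)


# ---------------------------------------------------------------- indices

def strength_series(result: TVPACResult) -> np.ndarray:
    """Network-summed prominent coupling strength per window."""
    out = np.zeros(result.n_windows)
    for series in result.modes.values():
        for w, m in enumerate(series):
            if m is not None:
                out[w] += m.strength
    return out


def transition_rate(label_sequence) -> float:
    """Fraction of consecutive-window opportunities with a mode change.

    Transitions are counted only between two consecutive windows that both
    carry a significant mode; the denominator is the total number of
    windows minus one.
    """
    labels = list(label_sequence)
    n = len(labels)
    sig = [l for l in labels if l is not None]
    if n < 2 or len(sig) < 2:
        return 0.0
    trans = sum(1 for a, b in zip(labels, labels[1:])
                if a is not None and b is not None and a != b)
    return trans / (n - 1)


def tr_matrix(result: TVPACResult) -> dict[tuple[int, int], float]:
    """Transition rate per pair, over band-pair mode labels."""
    return {pair: transition_rate(result.labels(pair))
            for pair in result.pairs}


def dier(modes_at_window, width_s: float) -> float:
    """Information exchange rate of one window: sum over pairs of
    (HF cycles / LF cycles).  HF cycles = amplitude-bin Hz x window width;
    LF cycles = complete cycles of the window's LF phase.  Pairs without a
    mode, or with zero LF cycles, contribute nothing."""
    total = 0.0
    for m in modes_at_window:
        if m is None or m.lf_cycles <= 0:
            continue
        total += (m.amp_hz * width_s) / m.lf_cycles
    return total


def wdier(modes_at_window, width_s: float) -> float:
    """dIER with each pair's ratio weighted by its coupling strength."""
    total = 0.0
    for m in modes_at_window:
        if m is None or m.lf_cycles <= 0:
            continue
        total += (m.amp_hz * width_s) / m.lf_cycles * m.strength
    return total


def _window_modes(result: TVPACResult, w: int):
    return [result.modes[p][w] for p in result.pairs]


def dier_series(result: TVPACResult) -> np.ndarray:
    w_s = result.windowing.width_s
    return np.array([dier(_window_modes(result, w), w_s)
                     for w in range(result.n_windows)])


def wdier_series(result: TVPACResult) -> np.ndarray:
    w_s = result.windowing.width_s
    return np.array([wdier(_window_modes(result, w), w_s)
                     for w in range(result.n_windows)])


@dataclass
class PDMatrix:
    """Empirical probability distribution of prominent band-pair modes."""

    bands: tuple[Band, ...]
    matrix: np.ndarray          # (n_bands, n_bands), rows = phase band

    @property
    def vector(self) -> np.ndarray:
        """Flattened upper-triangle view (28 entries for 8 bands)."""
        n = len(self.bands)
        iu = np.triu_indices(n, k=1)
        return self.matrix[iu]

    def support(self, min_probability: float = 0.0) -> int:
        """Number of band pairs above the occupancy threshold."""
        v = self.vector
        thr = max(min_probability, 0.0)
        return int((v > thr).sum()) if thr > 0 else int((v > 0).sum())


def pd_pac(modes, bands: tuple[Band, ...] = DEFAULT_BANDS,
           aggregate: str = "all") -> PDMatrix | list[PDMatrix]:
    """Distribution of prominent (phase band, amplitude band) pairs.

    ``modes`` is a TVPACResult or an iterable of mode sequences.
    ``aggregate`` is "all" (one matrix over pairs and windows) or
    "per_pair" (one matrix per mode sequence).
    """
    if isinstance(modes, TVPACResult):
        series = [modes.modes[p] for p in modes.pairs]
        bands = modes.grid.bands
    else:
        series = [list(s) for s in modes]
    names = [b.name for b in bands]

    def one(seqs):
        mat = np.zeros((len(bands), len(bands)))
        for seq in seqs:
            for m in seq:
                if m is None:
                    continue
                ab = band_of(m.amp_hz, bands)
                if ab is None:
                    continue
                mat[names.index(m.phase_band), names.index(ab.name)] += 1
        tot = mat.sum()
        return PDMatrix(tuple(bands), mat / tot if tot else mat)

    if aggregate == "all":
        return one(series)
    if aggregate == "per_pair":
        return [one([s]) for s in series]
    raise ValueError("aggregate must be 'all' or 'per_pair'")


def threshold_topography(values) -> np.ndarray:
    """Boolean mask of entries strictly above mean + 2 SD of the input set."""
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    return v > v.mean() + 2.0 * v.std()


# ------------------------------------------------------- sample entropy

def auto_mutual_information(x: np.ndarray, lag: int, bins: int = 16) -> float:
    """Histogram mutual information between x(t) and x(t+lag), in nats."""
    a, b = x[:-lag], x[lag:]
    h, _, _ = np.histogram2d(a, b, bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def choose_delay(x: np.ndarray, max_lag: int | None = None) -> int:
    """First local minimum of the auto-mutual-information curve."""
    n = x.size
    max_lag = max_lag or max(min(n // 4, 50), 2)
    ami = [auto_mutual_information(x, lag) for lag in range(1, max_lag + 1)]
    for k in range(1, len(ami) - 1):
        if ami[k] < ami[k - 1] and ami[k] <= ami[k + 1]:
            return k + 1
    return int(np.argmin(ami)) + 1


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    npts = x.size - (m - 1) * tau
    if npts < 2:
        raise ValueError("series too short for this embedding")
    return np.lib.stride_tricks.sliding_window_view(x, (m - 1) * tau + 1)[
        :, ::tau][:npts]


def choose_dimension(x: np.ndarray, tau: int, rtol: float = 10.0,
                     threshold: float = 0.05, m_max: int = 10) -> int:
    """Smallest dimension with a false-nearest-neighbour fraction below
    ``threshold`` (Kennel criterion, attractor-size test included)."""
    ra = x.std()
    for m in range(1, m_max):
        em = _embed(x, m, tau)
        em1 = _embed(x, m + 1, tau)
        npts = em1.shape[0]
        if npts < 10:
            return m
        pts = em[:npts]
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        nn = np.argmin(d2, axis=1)
        dm = np.sqrt(d2[np.arange(npts), nn])
        extra = np.abs(em1[np.arange(npts), -1] - em1[nn, -1])
        dm = np.maximum(dm, 1e-12)
        false = (extra / dm > rtol) | (np.sqrt(dm**2 + extra**2) / ra > 2.0)
        if false.mean() < threshold:
            return m
    return m_max


@dataclass(frozen=True)
class EntropyConfig:
    """Sample-entropy settings: embedding dimension, delay (samples) and
    tolerance as a fraction of the series SD."""

    m: int
    tau: int
    r: float = 0.2

    def __post_init__(self):
        if self.m < 1 or self.tau < 1 or self.r <= 0:
            raise ValueError("require m >= 1, tau >= 1, r > 0")


def sample_entropy(series, m: int | None = None, tau: int | None = None,
                   r: float = 0.2,
                   config: EntropyConfig | None = None) -> float:
    """Sample entropy: -ln(A/B) with Chebyshev template matching.

    A counts matched (m+1)-length templates, B matched m-length templates,
    both within tolerance ``r`` times the series SD, self-matches
    excluded.  With ``m`` or ``tau`` unset they are selected from the data
    (delay at the first minimum of auto-mutual information, dimension by
    false nearest neighbours); that auto mode needs >= 50 samples.
    Returns 0 for a constant series and +inf when no (m+1)-template pair
    matches; raises if no m-template pair matches.
    """
    x = np.asarray(series, float)
    if config is not None:
        m, tau, r = config.m, config.tau, config.r
    if x.std() == 0:
        return 0.0
    if m is None or tau is None:
        if x.size < 50:
            raise ValueError("auto embedding selection needs >= 50 samples")
        tau = tau or choose_delay(x)
        m = m or choose_dimension(x, tau)
    tol = r * x.std()
    em1 = _embed(x, m + 1, tau)
    npts = em1.shape[0]
    em = _embed(x, m, tau)[:npts]     # same template count at both lengths

    def matches(e):
        d = np.abs(e[:, None, :] - e[None, :, :]).max(-1)
        iu = np.triu_indices(e.shape[0], k=1)
        return int((d[iu] <= tol).sum())

    B = matches(em)
    A = matches(em1)
    if B == 0:
        raise ValueError("no template matches at length m; increase r")
    if A == 0:
        return float("inf")
    return float(-np.log(A / B))
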