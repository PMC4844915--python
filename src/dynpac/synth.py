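"""Synthetic multichannel recordings with known phase-amplitude coupling.

The generator plants, per channel pair, epochs in which the phase of a
low-frequency (LF) stochastic oscillation on one channel modulates the
amplitude envelope of a high-frequency (HF) carrier on the other:

    x_lf(t) = cos(phi_m(t))
    x_hf(t) = [1 + chi * cos(phi_m(t) - phase_lag)] * sin(2*pi*f_amp*t)

``phi_m`` is the phase of narrowband-filtered Gaussian noise spanning the
modulator's frequency band, so the modulating rhythm decoheres over a few
cycles the way cortical rhythms do.  This stochasticity is essential: a
constant-frequency modulator is invariant (up to rotation) under the
cut-swap surrogate used downstream, which would make planted couplings
untestable by construction.

Every channel also receives a constant-amplitude alpha rhythm (10 Hz,
random phase) plus white noise.  The alpha line keeps the broadband
spectral peak away from the modulating frequency, which the power-
separation criterion of the PAC stage requires before it will accept a
coupling.  A 1/f background is available as an option instead.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .bands import DEFAULT_BANDS, Band, band_of
from .recording import Recording

__all__ = [
    "CouplingEpoch", "ModeSchedule", "SimulationSpec", "GroupArchetype",
    "NI_LIKE", "RD_LIKE", "simulate_coupled_pair", "simulate_recording",
    "make_cohort", "CohortSubject",
]


@dataclass(frozen=True)
class CouplingEpoch:
    """One interval of phase-amplitude coupling between a channel pair."""

    start_s: float
    end_s: float
    f_phase: float      # Hz, modulating oscillation
    f_amp: float        # Hz, modulated carrier
    chi: float          # modulation depth in [0, 1]
    phase_lag: float = math.pi / 4   # radians between LF phase and envelope
    mod_bw: float | None = None      # modulator bandwidth; None -> full band

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValueError("epoch must have end_s > start_s")
        if not 0.0 <= self.chi <= 1.0:
            raise ValueError("chi must lie in [0, 1]")
        if not self.f_amp > self.f_phase:
            raise ValueError("f_amp must exceed f_phase")


@dataclass(frozen=True)
class ModeSchedule:
    """Ordered, non-overlapping coupling epochs for one directed pair."""

    pair: tuple[int, int]            # (phase channel, amplitude channel)
    epochs: tuple[CouplingEpoch, ...]

    def __post_init__(self):
        eps = tuple(sorted(self.epochs, key=lambda e: e.start_s))
        object.__setattr__(self, "epochs", eps)
        for a, b in zip(eps, eps[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"overlapping epochs for pair {self.pair}: "
                    f"[{a.start_s},{a.end_s}) and [{b.start_s},{b.end_s})")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic recording."""

    n_channels: int
    duration_s: float
    rate_hz: float = 256.0
    schedules: tuple[ModeSchedule, ...] = ()
    noise_sd: float = 0.5
    background: str = "alpha"        # "alpha" | "pink" | "none"
    background_amp: float = 1.0
    background_hz: float = 10.0
    leakage: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        fmax = max((e.f_amp for s in self.schedules for e in s.epochs),
                   default=0.0)
        if fmax and self.rate_hz < 4 * fmax:
            raise ValueError("rate_hz must be at least 4x the fastest carrier")
        for s in self.schedules:
            i, j = s.pair
            if not (0 <= i < self.n_channels and 0 <= j < self.n_channels):
                raise ValueError(f"schedule pair {s.pair} outside channel range")
        if self.leakage is not None:
            L = np.asarray(self.leakage, float)
            if L.shape != (self.n_channels, self.n_channels):
                raise ValueError("leakage matrix must be n_channels x n_channels")
            if not np.allclose(np.diag(L), 1.0):
                raise ValueError("leakage matrix must have unit diagonal")


@dataclass(frozen=True)
class GroupArchetype:
    """Generative contrast between stable/narrow and switching/broad subjects."""

    label: str
    repertoire: tuple[tuple[float, float], ...]   # (f_phase, f_amp) modes
    mean_dwell_s: float                           # inf -> one epoch per pair
    chi_range: tuple[float, float]
    n_coupled_pairs: int = 1


#: Stable narrow-repertoire archetype: one theta->gamma mode held throughout.
NI_LIKE = GroupArchetype(
    label="NI-like",
    repertoire=((6.0, 40.0),),
    mean_dwell_s=math.inf,
    chi_range=(0.55, 0.75),
    n_coupled_pairs=1,
)

#: Switching broad-repertoire archetype: four modes, exponential dwell times.
#: Carriers sit mid-band so the detected band-pair label is stable; see
#: the methods note for why the repertoire favours gamma carriers.
RD_LIKE = GroupArchetype(
    label="RD-like",
    repertoire=((2.0, 25.0), (2.0, 40.0), (6.0, 36.0), (12.0, 42.0)),
    mean_dwell_s=8.0,
    chi_range=(0.75, 0.95),
    n_coupled_pairs=3,
)


def modulator_phase(f_phase: float, n: int, rate_hz: float,
                    rng: np.random.Generator, mod_bw: float | None = None,
                    bands: tuple[Band, ...] = DEFAULT_BANDS) -> np.ndarray:
    """Unwrapped phase of a narrowband stochastic oscillation around f_phase.

    With ``mod_bw=None`` the passband is the full frequency band containing
    ``f_phase`` (e.g. 4-8 Hz for a 6 Hz theta modulator).
    """
    if mod_bw is None:
        b = band_of(f_phase, bands)
        lo, hi = (b.low, b.high) if b else (f_phase * 0.75, f_phase * 1.25)
    else:
        lo, hi = f_phase - mod_bw / 2.0, f_phase + mod_bw / 2.0
    lo = max(lo, 0.05)
    if hi >= rate_hz / 2:
        raise ValueError("modulator band exceeds Nyquist")
    # pad so filter/Hilbert transients do not enter the returned phase
    pad = int(2.0 * rate_hz)
    w = rng.standard_normal(n + 2 * pad)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")
    x = sps.sosfiltfilt(sos, w)
    z = sps.hilbert(x)
    return np.unwrap(np.angle(z))[pad:pad + n]


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    x = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) / np.sqrt(f), n)
    sd = x.std()
    return x / sd if sd else x


def _background(n: int, rate_hz: float, rng: np.random.Generator,
                kind: str, amp: float, freq: float) -> np.ndarray:
    """Resting background: an alpha line, 1/f noise, or their mixture."""
    if kind == "none" or amp == 0:
        return np.zeros(n)
    t = np.arange(n) / rate_hz
    alpha = amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    if kind == "alpha":
        return alpha
    if kind == "pink":
        return amp * pink_noise(n, rng)
    if kind == "alpha+pink":
        return alpha + 0.75 * amp * pink_noise(n, rng)
    raise ValueError(f"unknown background kind {kind!r}")


def _ramp(n: int, ramp: int) -> np.ndarray:
    """Unit window with raised-cosine on/off ramps."""
    w = np.ones(n)
    r = min(ramp, n // 2)
    if r > 0:
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        w[:r] = edge
        w[-r:] = edge[::-1]
    return w


def simulate_coupled_pair(epoch: CouplingEpoch, duration_s: float,
                          rate_hz: float = 256.0, noise_sd: float = 0.5,
                          seed: int = 0, background: str = "alpha",
                          background_amp: float = 1.0,
                          background_hz: float = 10.0,
                          return_phase: bool = False):
    """Two channels with the epoch's coupling active over the whole duration.

    Channel A carries the LF modulating oscillation, channel B the
    amplitude-modulated HF carrier.  Both receive background rhythm and
    independent Gaussian noise.  With ``return_phase`` the modulator's
    ground-truth phase series is returned as a third element.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if epoch.f_amp >= rate_hz / 2:
        raise ValueError("f_amp at or above Nyquist would alias")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    ph = modulator_phase(epoch.f_phase, n, rate_hz, rng, epoch.mod_bw)
    a = np.cos(ph)
    carrier = np.sin(2 * np.pi * epoch.f_amp * t + rng.uniform(0, 2 * np.pi))
    b = (1.0 + epoch.chi * np.cos(ph - epoch.phase_lag)) * carrier
    a = a + _background(n, rate_hz, rng, background, background_amp, background_hz)
    b = b + _background(n, rate_hz, rng, background, background_amp, background_hz)
    a = a + noise_sd * rng.standard_normal(n)
    b = b + noise_sd * rng.standard_normal(n)
    if return_phase:
        return a, b, ph
    return a, b


def simulate_recording(spec: SimulationSpec
                       ) -> tuple[Recording, tuple[ModeSchedule, ...]]:
    """Realize a SimulationSpec; returns the recording and its ground truth.

    Channels without schedules contain background + noise only.  Scheduled
    epochs are inserted with 0.25-s raised-cosine ramps.  The optional
    leakage matrix is applied as instantaneous linear mixing after
    synthesis.  Deterministic for a fixed spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate_hz))
    t = np.arange(n) / spec.rate_hz
    data = np.zeros((n, spec.n_channels))
    for ch in range(spec.n_channels):
        data[:, ch] += _background(n, spec.rate_hz, rng, spec.background,
                                   spec.background_amp, spec.background_hz)
    ramp = int(0.25 * spec.rate_hz)
    for sched in spec.schedules:
        i, j = sched.pair
        for ep in sched.epochs:
            if ep.f_amp >= spec.rate_hz / 2:
                raise ValueError("f_amp at or above Nyquist would alias")
            s0 = int(round(ep.start_s * spec.rate_hz))
            s1 = min(int(round(ep.end_s * spec.rate_hz)), n)
            if s1 <= s0:
                continue
            m = s1 - s0
            ph = modulator_phase(ep.f_phase, m, spec.rate_hz, rng, ep.mod_bw)
            w = _ramp(m, ramp)
            tt = t[s0:s1]
            carrier = np.sin(2 * np.pi * ep.f_amp * tt + rng.uniform(0, 2 * np.pi))
            data[s0:s1, i] += w * np.cos(ph)
            data[s0:s1, j] += w * (1.0 + ep.chi * np.cos(ph - ep.phase_lag)) * carrier
    data += spec.noise_sd * rng.standard_normal(data.shape)
    if spec.leakage is not None:
        data = data @ np.asarray(spec.leakage, float).T
    rec = Recording(data, spec.rate_hz)
    return rec, spec.schedules


@dataclass
class CohortSubject:
    recording: Recording
    label: str
    schedules: tuple[ModeSchedule, ...]
    seed: int


def _subject_schedules(arch: GroupArchetype, spec: SimulationSpec,
                       rng: np.random.Generator,
                       min_dwell_s: float = 2.0) -> tuple[ModeSchedule, ...]:
    pairs = [(2 * k, 2 * k + 1) for k in range(arch.n_coupled_pairs)]
    if pairs and max(p[1] for p in pairs) >= spec.n_channels:
        raise ValueError("archetype needs more channels than the spec provides")
    schedules = []
    for pair in pairs:
        epochs = []
        if math.isinf(arch.mean_dwell_s):
            f_p, f_a = arch.repertoire[rng.integers(len(arch.repertoire))]
            chi = rng.uniform(*arch.chi_range)
            epochs.append(CouplingEpoch(0.0, spec.duration_s, f_p, f_a, chi))
        else:
            t0, prev = 0.0, None
            while t0 < spec.duration_s:
                dwell = max(rng.exponential(arch.mean_dwell_s), min_dwell_s)
                t1 = min(t0 + dwell, spec.duration_s)
                choices = [m for m in arch.repertoire if m != prev]
                mode = choices[rng.integers(len(choices))]
                chi = rng.uniform(*arch.chi_range)
                epochs.append(CouplingEpoch(t0, t1, mode[0], mode[1], chi))
                prev, t0 = mode, t1
        schedules.append(ModeSchedule(pair, tuple(epochs)))
    return tuple(schedules)


def make_cohort(n_per_group: int,
                archetypes: tuple[GroupArchetype, ...] = (NI_LIKE, RD_LIKE),
                base_spec: SimulationSpec | None = None,
                seed: int = 0) -> list[CohortSubject]:
    """Simulate a labelled cohort of n_per_group subjects per archetype.

    Per-subject seeds derive deterministically from the master seed.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    if base_spec is None:
        base_spec = SimulationSpec(n_channels=6, duration_s=60.0)
    master = np.random.default_rng(seed)
    subjects = []
    for arch in archetypes:
        for _ in range(n_per_group):
            sub_seed = int(master.integers(2**31))
            rng = np.random.default_rng(sub_seed)
            schedules = _subject_schedules(arch, base_spec, rng)
            spec = replace(base_spec, schedules=schedules, seed=sub_seed)
            rec, truth = simulate_recording(spec)
            subjects.append(CohortSubject(rec, arch.label, truth, sub_seed))
    return subjects
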