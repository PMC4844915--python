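"""Windowing, transition rate, information exchange rates, PD, entropy."""
import numpy as np
import pytest

import dynpac as dp
from dynpac.dynamics import PDMatrix, ProminentMode, dier, wdier


# ------------------------------------------------------------ windows

@pytest.mark.parametrize("dur,width,step,count", [
    (2.0, 2.0, 0.5, 1),
    (180.0, 2.0, 0.5, 357),
    (10.0, 2.0, 0.5, 17),
])
def test_window_counts(dur, width, step, count):
    spec = dp.WindowingSpec(width, step)
    assert len(dp.make_windows(dur, spec)) == count


def test_window_validation():
    with pytest.raises(ValueError):
        dp.make_windows(1.0, dp.WindowingSpec(2.0, 0.5))
    with pytest.raises(ValueError):
        dp.WindowingSpec(2.0, 3.0)


# ------------------------------------------------------ transition rate

def test_transition_rate_worked_example():
    seq = [("delta", "theta"), ("theta", "gamma"),
           ("theta", "gamma"), ("beta1", "gamma")]
    assert dp.transition_rate(seq) == pytest.approx(2 / 3)


def test_transition_rate_edge_rules():
    assert dp.transition_rate(["A"] * 17) == 0.0
    assert dp.transition_rate(["A", None, "A", "A"]) == 0.0
    assert dp.transition_rate(["A", None]) == 0.0
    assert dp.transition_rate([]) == 0.0


def test_transition_rate_label_invariant(rng):
    seq = [("a", int(k)) for k in rng.integers(0, 3, 40)]
    relabeled = [{0: "x", 1: "yy", 2: (9, 9)}[k[1]] for k in seq]
    assert dp.transition_rate(seq) == dp.transition_rate(relabeled)


# ---------------------------------------------------------- dIER/wdIER

def _mode(amp, cycles, strength=0.21):
    return ProminentMode("delta", amp, strength, cycles)


def test_dier_worked_example():
    assert dier([_mode(14, 2)], width_s=2.0) == pytest.approx(14.0)
    assert wdier([_mode(14, 2, 0.21)], width_s=2.0) == pytest.approx(2.94)


def test_dier_additivity_and_none_handling():
    assert dier([_mode(14, 2), _mode(14, 2)], 2.0) == pytest.approx(28.0)
    assert dier([None, None], 2.0) == 0.0
    assert dier([_mode(14, 0)], 2.0) == 0.0    # zero LF cycles contribute 0


def test_wdier_weight_identities(rng):
    modes = [_mode(int(a), int(c), s) for a, c, s in
             zip(rng.integers(10, 45, 6), rng.integers(1, 5, 6),
                 rng.uniform(0, 1, 6))]
    assert wdier(modes, 2.0) <= dier(modes, 2.0) + 1e-12
    ones = [m._replace(strength=1.0) for m in modes]
    assert wdier(ones, 2.0) == pytest.approx(dier(ones, 2.0))
    zeros = [m._replace(strength=0.0) for m in modes]
    assert wdier(zeros, 2.0) == 0.0


def test_dier_matches_naive_loop(rng):
    """Oracle: explicit per-pair loop over the defining ratio."""
    modes = [_mode(int(a), int(c), float(s)) if a % 3 else None
             for a, c, s in zip(rng.integers(5, 45, 20),
                                rng.integers(1, 6, 20), rng.uniform(0, 1, 20))]
    width = 2.0
    ref_d = ref_w = 0.0
    for m in modes:
        if m is None or m.lf_cycles == 0:
            continue
        hf_cycles = m.amp_hz * width
        ref_d += hf_cycles / m.lf_cycles
        ref_w += hf_cycles / m.lf_cycles * m.strength
    assert dier(modes, width) == pytest.approx(ref_d)
    assert wdier(modes, width) == pytest.approx(ref_w)


# ------------------------------------------------------------------ PD

def test_pd_one_hot_and_empty():
    seq = [ProminentMode("theta", 9, 0.4, 2)] * 10
    pd = dp.pd_pac([seq])
    assert pd.matrix.sum() == pytest.approx(1.0)
    names = [b.name for b in pd.bands]
    assert pd.matrix[names.index("theta"), names.index("alpha1")] == 1.0
    assert pd.vector.shape == (28,)
    empty = dp.pd_pac([[None] * 10])
    assert np.allclose(empty.matrix, 0.0)


def test_pd_support_counting():
    mat = np.zeros((8, 8))
    mat[0, 1] = 0.6
    mat[0, 2] = 0.3
    mat[1, 2] = 0.1
    pd = PDMatrix(dp.DEFAULT_BANDS, mat)
    assert pd.support() == 3
    assert pd.support(0.2) == 2


# ------------------------------------------------------------ topography

def test_threshold_topography_rules(rng):
    assert not dp.threshold_topography(np.full(50, 3.3)).any()
    vals = np.zeros(100)
    vals[17] = 10.0
    assert dp.threshold_topography(vals).nonzero()[0].tolist() == [17]
    g = rng.standard_normal(1000)
    frac = dp.threshold_topography(g).mean()
    assert 0.01 < frac < 0.04          # ~2.3% beyond mean + 2 SD
    with pytest.raises(ValueError):
        dp.threshold_topography([1.0, 2.0])


# -------------------------------------------------------- sample entropy

def test_sample_entropy_constant_is_zero():
    assert dp.sample_entropy(np.ones(100), m=2, tau=1) == 0.0


def test_sample_entropy_orders_noise_above_sine(rng):
    wins = 0
    for _ in range(20):
        noise = rng.standard_normal(200)
        t = np.arange(200)
        sine = np.sin(2 * np.pi * t / 25 + rng.uniform(0, 6))
        if dp.sample_entropy(noise, m=2, tau=1) > \
           dp.sample_entropy(sine, m=2, tau=1):
            wins += 1
    assert wins >= 18


def test_shuffling_does_not_decrease_entropy(rng):
    t = np.arange(150)
    x = np.sin(2 * np.pi * t / 30)
    h0 = dp.sample_entropy(x, m=2, tau=1)
    higher = sum(dp.sample_entropy(rng.permutation(x), m=2, tau=1) >= h0
                 for _ in range(10))
    assert higher == 10


def test_sample_entropy_matches_direct_counting(rng):
    """Oracle: direct O(n^2) template counting on a 100-sample series."""
    x = rng.standard_normal(100)
    m, tau, r = 2, 1, 0.2
    tol = r * x.std()
    npts = len(x) - m * tau
    B = A = 0
    for i in range(npts):
        for j in range(i + 1, npts):
            if max(abs(x[i + k * tau] - x[j + k * tau]) for k in range(m)) <= tol:
                B += 1
                if max(abs(x[i + k * tau] - x[j + k * tau])
                       for k in range(m + 1)) <= tol:
                    A += 1
    expected = -np.log(A / B)
    assert dp.sample_entropy(x, m=m, tau=tau, r=r) == pytest.approx(expected)


def test_sample_entropy_degenerate_counts():
    # strictly monotone series with tiny tolerance: no m-template matches
    with pytest.raises(ValueError):
        dp.sample_entropy(np.arange(30.0), m=2, tau=1, r=0.001)


def test_auto_embedding_selection(rng):
    t = np.arange(400)
    x = np.sin(2 * np.pi * t / 40) + 0.05 * rng.standard_normal(400)
    from dynpac.dynamics import choose_delay, choose_dimension
    tau = choose_delay(x)
    assert 5 <= tau <= 20              # near quarter period of 10
    m = choose_dimension(x, tau)
    assert 1 <= m <= 4
    val = dp.sample_entropy(x)         # auto mode runs end to end
    assert np.isfinite(val) and val >= 0


# ------------------------------------------------------ engine behaviour

def test_tvpac_isolates_the_coupled_pair():
    eps = (dp.CouplingEpoch(0.0, 20.0, 6.0, 40.0, 0.85),)
    spec = dp.SimulationSpec(n_channels=4, duration_s=20.0,
                             schedules=(dp.ModeSchedule((0, 1), eps),), seed=4)
    rec, _ = dp.simulate_recording(spec)
    res = dp.build_tvpac(rec, pairs=[(0, 1), (2, 3), (3, 3)],
                         surrogate=dp.SurrogateConfig(n_surrogates=200, seed=4))
    n_coupled = sum(m is not None for m in res.modes[(0, 1)])
    n_noise = sum(m is not None for m in res.modes[(2, 3)])
    n_diag = sum(m is not None for m in res.modes[(3, 3)])
    assert n_coupled > 0.5 * res.n_windows
    assert n_noise < 0.25 * res.n_windows
    assert n_diag < 0.25 * res.n_windows
    labels = [l for l in res.labels((0, 1)) if l is not None]
    hits = sum(l == ("theta", "gamma") for l in labels)
    assert hits >= 0.75 * len(labels)


def test_strength_series_shapes(coupled_tvpac):
    s = dp.strength_series(coupled_tvpac)
    d = dp.dier_series(coupled_tvpac)
    w = dp.wdier_series(coupled_tvpac)
    assert s.shape == d.shape == w.shape == (coupled_tvpac.n_windows,)
    assert np.all(s >= 0) and np.all(w <= d + 1e-9)
    on = s > 0
    assert np.all((d > 0) == on)


def test_orthogonalization_suppresses_leakage_duplicates():
    """Zero-lag mixing copies a genuine coupling into the reverse-direction
    pair; orthogonalizing the amplitude channel against the phase channel
    removes those spurious duplicates."""
    eps = (dp.CouplingEpoch(0.0, 14.0, 6.0, 40.0, 0.85),)
    L = np.eye(2)
    L[0, 1] = L[1, 0] = 0.2
    spec = dp.SimulationSpec(n_channels=2, duration_s=14.0,
                             schedules=(dp.ModeSchedule((0, 1), eps),),
                             leakage=L, seed=6)
    rec, _ = dp.simulate_recording(spec)

    def theta_gamma_count(orthogonalize):
        res = dp.build_tvpac(
            rec, pairs=[(1, 0)], orthogonalize=orthogonalize,
            surrogate=dp.SurrogateConfig(n_surrogates=200, seed=6))
        return sum(l == ("theta", "gamma")
                   for l in res.labels((1, 0)) if l is not None)

    plain = theta_gamma_count(False)
    corrected = theta_gamma_count(True)
    assert plain >= 1            # leakage fabricates the reverse coupling
    assert corrected < plain     # correction suppresses it


def test_tvpac_unaligned_step_fallback(coupled_fixture):
    """A step that does not divide the decimation grid takes the exact
    cumulative-sum path and still recovers the planted mode."""
    _, a, b, _ = coupled_fixture
    rec = dp.Recording(np.column_stack([a, b]), 256.0)
    res = dp.build_tvpac(
        rec, pairs=[(0, 1)], windowing=dp.WindowingSpec(2.0, 0.7),
        surrogate=dp.SurrogateConfig(n_surrogates=100, seed=1))
    labels = [l for l in res.labels((0, 1)) if l is not None]
    assert len(labels) >= 5
    assert sum(l == ("theta", "gamma") for l in labels) >= 0.6 * len(labels)


def test_entropy_config_equivalent_to_kwargs(rng):
    from dynpac.dynamics import EntropyConfig
    x = rng.standard_normal(120)
    cfg = EntropyConfig(m=2, tau=1, r=0.2)
    assert dp.sample_entropy(x, config=cfg) == \
        dp.sample_entropy(x, m=2, tau=1, r=0.2)
    with pytest.raises(ValueError):
        EntropyConfig(m=0, tau=1)
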