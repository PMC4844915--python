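# Methods

`dynpac` implements a dynamic cross-frequency coupling analysis for
multichannel electrophysiological recordings: sliding-window
phase-amplitude coupling (PAC) graphs with surrogate-based significance,
the temporal-variability indices derived from them, and classification
of subjects from those dynamic profiles.  This note records the model,
the numerical choices, and what the synthetic benchmarks do and do not
establish.

## The coupling model and its estimator

Phase-amplitude coupling is the modulation of a fast oscillation's
amplitude envelope by the phase of a slower rhythm.  For a directed
sensor pair (i, j), a phase band `f_phi` and a 1-Hz amplitude bin `f_a`,
the estimator chain is

1. band-pass channel i in the phase band; the Hilbert phase is
   `phi_LF(t)`;
2. band-pass channel j around the amplitude bin, take the Hilbert
   envelope `A_HF(t)`;
3. band-pass that envelope in the phase band; its Hilbert phase
   `phi_LF->HF(t)` carries the rhythm at which the envelope waxes and
   wanes;
4. form `dphi(t) = phi_LF(t) - phi_LF->HF(t)` and average the unit
   phasors:  PLV = |mean exp(i dphi)|, and the default coupling strength
   iPLV = |Im mean exp(i dphi)|.

iPLV discards zero-lag phase agreement, which is what instantaneous
field spread produces, at the cost of scaling genuine coupling by
|sin(lag)|.  A pairwise orthogonalization step (removing, per sample,
the component of one band-limited analytic signal in phase with the
other) is available for sensor data with linear mixing.

The comodulogram evaluates 217 cells: seven modulating bands
(delta 0.5-4, theta 4-8, alpha1 8-10, alpha2 10-13, beta1 13-15,
beta2 15-19, beta3 20-29 Hz) against integer amplitude bins 1-45 Hz,
a bin being eligible only above its row's band edge (41+37+35+32+30+26+16
cells).  Gamma (30-45 Hz) never acts as a modulator.

### Amplitude-bin filter bandwidth

An amplitude-modulated carrier has sidebands at `f_a ± f_phi`.  A filter
that fails to pass at least one sideband together with the carrier
removes the modulation from the envelope entirely, and a filter narrower
than the phase band leaves the envelope unable to fluctuate at the
band's own frequencies, which degrades every statistic computed from its
phase.  The per-row half-width is therefore `max(1, band midpoint)` Hz
(e.g. ±2.25 Hz for delta rows, ±6 Hz for theta rows), with the low edge
clamped above the phase band.  A scalar override is available.

A consequence worth stating plainly: the iPLV value of a cell depends on
the *ratio* of coherent to incoherent envelope content, and filter gain
cancels from that ratio.  All bins whose filter passes the carrier plus
a sideband therefore show nearly the same coupling value (measured
spread across such a plateau: under 0.02 for a mid-gamma carrier), and
the argmax bin within the plateau is decided by estimation noise.  The
amplitude *band* of a coupling is identifiable; the exact 1-Hz bin is
identifiable only up to the plateau half-width.  Downstream indices
treat modes at (phase band, amplitude band) granularity accordingly,
while the reported bin feeds the cycle-count ratios below.

## Sliding-window graphs and significance

Windows are 2 s wide (two cycles of the slowest delta activity) and
advance in 0.5-s steps; the window count follows the data length
(`floor((duration - width)/step) + 1`).  Filtering and analytic signals
are computed once over the full record and sliced per window; windows
within 2 s of the record edges are discarded because filter and Hilbert
transients there masquerade as coupling (measured to inflate
false-positive rates several-fold).

Null distributions use cut-swap surrogates: the low-frequency phase
series is cut at one random point and the two segments exchanged, which
is a circular shift pairing the window's envelope phase with LF phase
from elsewhere in the record.  Shifts are at least one window long and
circular over the transient-trimmed interior.  Per cell, the one-sided
empirical p-value is the fraction of surrogate values at or above the
observed one (the `proportion` convention; an add-one variant is
available), and the 217 cells of a (pair, window) comodulogram are
corrected with Benjamini-Hochberg at q = 0.01.  The default surrogate
count is 1000.

Two properties of this construction matter in practice:

* **Resolution.**  Empirical p-values cannot fall below 1/n (or
  1/(n+1)).  With the proportion convention, rejections at q = 0.01 over
  217 cells are effectively the cells that beat *every* surrogate.  The
  distinct information in the surrogate family is bounded by the number
  of phase-coherence times per record, so short records cap the
  attainable specificity regardless of the surrogate count: three-minute
  records carry a few hundred effective draws, 20-s records a few dozen.
  The false-positive calibration check therefore runs on full-length
  (3-min) noise records with `n = ceil(m/q)` surrogates, the count at
  which the step-up rule's nominal level is meaningful; the add-one
  convention at smaller counts gives a conservative (sub-nominal) rate
  instead.
* **Power separation.**  A coupling whose modulating frequency equals
  the record's dominant spectral peak is likely power- rather than
  phase-driven.  Rows whose band-filtered spectral peak lies within 1 Hz
  of the broadband (0.5-45 Hz) peak of the phase channel are excluded
  per window.

### Prominent-mode decision

Significant cells are integrated within each of the 28 (phase band,
amplitude band) pairs: the window's prominent mode is the band pair with
the largest summed iPLV over its significant bins, provided it holds at
least three of them; the mode's 1-Hz bin is its strongest significant
bin.  The minimum-bin rule reflects the plateau physics above -- a
genuine band-level coupling excites several overlapping bins at once,
whereas an isolated single-bin exceedance is the signature of a
finite-resolution surrogate floor.  A raw single-bin argmax
(`mode_selection="bin_max"`, the literal argmax rule) is retained;
measured on the planted-coupling benchmark it is ~8 points less precise
than band integration.

## Temporal-variability indices

* **Strength series** -- prominent iPLV summed over all pairs per
  window.
* **Transition rate** -- label changes between consecutive windows that
  both carry a significant mode, divided by (windows - 1); labels are
  band pairs.  0 <= TR <= 1.
* **dIER / wdIER** -- per window, the sum over pairs of (HF cycles / LF
  cycles): HF cycles = amplitude-bin frequency x window width; LF cycles
  = complete 2-pi wraps of the window's band-filtered LF phase (an
  observable, since the modulating side is band- not bin-resolved).
  wdIER weights each ratio by the mode's iPLV, hence wdIER <= dIER.
* **PD matrix** -- empirical probabilities of the 28 band-pair modes
  aggregated over windows and pairs.  Its *support* is the repertoire;
  because empirical-p floors scatter a low-rate background over many
  cells, repertoire size comparisons use either an occupancy threshold
  or the participation ratio `1 / sum(p^2)` (the effective number of
  occupied modes), which is robust to a flat background.
* **Topographic thresholding** -- entries above mean + 2 SD of the
  value set.
* **Sample entropy** -- -ln(A/B) with Chebyshev template matching at
  tolerance 0.2 SD, self-matches excluded.  Auto-selection: delay at the
  first minimum of the 16-bin auto-mutual-information, dimension by
  false nearest neighbours (Rtol = 10, threshold 5%, capped at 10).

## Group analysis

dIER/wdIER trajectories are compared after time-delay embedding with the
Wald-Wolfowitz / Friedman-Rafsky statistic: label runs R on the
Euclidean minimum spanning tree of the pooled clouds, standardized with
the Friedman-Rafsky null moments and sign-flipped so that larger values
mean more dissimilar; the k-NN classifier consumes it floored at zero.
TR matrices and PD vectors use Euclidean distance.  `TrajectoryKNN` is a
scikit-learn estimator (k = 9 by default, the midpoint of the robust
7-11 range; ties break toward the smaller summed distance).  Validation
schemes: leave-one-subject-out; stratified random two-fold (repeated);
and split-half variants in which every feature is recomputed on each
half of the window series.  Group comparisons use the two-sided Wilcoxon
rank-sum (exact for small tie-free samples) and partial correlation via
least-squares residualization with a t reference on n - 2 - c degrees of
freedom.

## The synthetic-data generator

Each scheduled coupling epoch plants

    x_phase(t) = cos(phi_m(t)),
    x_amp(t)   = [1 + chi * cos(phi_m(t) - lag)] * sin(2*pi*f_a*t),

where `phi_m` is the phase of narrowband-filtered Gaussian noise
spanning the modulator's band.  The stochastic modulator is essential,
not decorative: a constant-frequency modulator is invariant up to
rotation under the cut-swap, so the surrogate test would see the
coupling in every surrogate and planted modes could never reach
significance.  The default lag is pi/4 (iPLV is blind at lag 0).  Every
channel receives a constant-amplitude 10 Hz alpha rhythm with random
phase plus white noise (SD 0.5); the alpha line keeps the broadband
spectral peak away from the modulating frequency, without which the
power-separation criterion would discard every planted mode.  A 1/f
background is available but not default -- it degrades low-band phase
estimation and can itself capture the broadband peak.

Cohort archetypes contrast a stable/narrow profile (one coupled pair,
one theta->gamma mode held for the whole record, chi 0.55-0.75) with a
switching/broad profile (three coupled pairs, four modes spanning
delta/theta/alpha2 modulators, exponential dwell times with 8-s mean
truncated at 2 s, chi 0.75-0.95).  Carriers sit mid-gamma because gamma
is the only amplitude band wide enough to contain a detection plateau
without spilling across band edges.  Per-subject seeds derive from the
master seed, so cohorts are reproducible end to end.

What the generator does **not** emulate: realistic sensor geometry and
forward fields, 1/f-dominant spectra, physiological artifacts, or
asymmetric (non-sinusoidal) slow rhythms.  Passing benchmarks on this
generator demonstrates that the pipeline recovers what it is defined to
recover under its own assumptions; it does not certify performance on
recorded data.

## Known limitations

* Delta-band windows contain only two modulator cycles, so both the
  estimator and its null have few effective degrees of freedom there;
  planted delta modes are detected at visibly lower rates than theta or
  alpha modes, and the narrow 2-3-Hz-wide bands (alpha1, alpha2, beta1)
  have heavy-tailed chance iPLV values for the same reason.  These are
  properties of 2-s windows and the band scheme, not implementation
  artifacts.
* Surrogate specificity is record-length-limited (see Resolution above).
* Pairwise orthogonalization is an instantaneous projection: it removes
  leakage-fabricated couplings (e.g. the reverse-direction duplicate a
  zero-lag mixing matrix creates), but it also suppresses genuine
  coupling whenever the modulated carrier leaks into the phase channel,
  and the amplitude-dependent removal can distort envelopes in the
  narrow phase-band rows.  It is off by default and intended for sensor
  data with appreciable linear mixing.
* The engine computes window statistics from phasor products decimated
  8-fold; products of same-band phasors are band-limited well below the
  decimated Nyquist for every band of the default scheme, and decimated
  means match exact means to about a percent.  The engine's zero-phase
  filters are applied spectrally (|H|^2 of the third-order Butterworth);
  the window-level operations in `dynpac.pac` use time-domain
  forward-backward filtering, and the two agree away from record edges.

## Benchmark scales

The shipped tests run the full pipeline at desk scale: 20-s two-channel
fixtures (50 seeds) for planted-mode recovery, eight 3-minute noise
records (200 windows) for false-positive calibration, and a 10 + 10
cohort of 6-channel, 60-s subjects for classification and the
directional group effects, with 200 surrogates per comodulogram in the
simulation-heavy checks and the full n = ceil(m/q) resolution in the
calibration check.
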