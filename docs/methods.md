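# Methods

This note documents the models, estimators, defaults and numerical choices
implemented in `laminet`, and what the synthetic-data tests do and do not
establish about real recordings.

## Signal model and preprocessing

Recordings are multichannel extracellular voltage series from a single-shank
laminar probe; the reference geometry is 16 sites at 100 µm spacing with the
tip at 1600 µm, spanning cortical layers L1–L5/6 and hippocampal CA1.
Conventions fixed at every module boundary: times in seconds, phases in
degrees in [−180, 180) with 0° at the positive peak of a band-limited
oscillation and ±180° at its trough, channel 0 shallowest.

* **LFP stream**: 2nd-order Butterworth band-pass 0.4–300 Hz.
* **Spike stream**: Butterworth band-pass 0.3–5 kHz; the order is not
  dictated by the estimator, so it defaults to 2 to match the LFP filter
  (configurable).
* All filters are applied forward–backward (`sosfiltfilt`), i.e. zero
  phase.  This is a requirement, not a preference: every downstream
  statistic compares phase across channels and frequencies, and a causal
  filter's group delay would bias preferred phases and directional
  comparisons.
* **Spike detection**: threshold at mean − 3.5 SD of the spike-band signal,
  spikes at negative-going crossings, with a 1 ms refractory lockout to
  avoid double-counting multiphasic waveforms.  The threshold is
  mean-relative, hence translation-invariant.
* **Instantaneous phase**: Hilbert transform of the signal band-passed at
  the target band.  For per-frequency phase on a 0.5 Hz grid the band is
  f ± 0.5 Hz — matched to the grid spacing.  A wider band (e.g. ±1 Hz)
  makes neighbouring grid cells statistically indistinguishable because the
  gentle 2nd-order rolloff passes the same oscillation into several bands,
  destroying the frequency resolution of the comodulogram argmax.
* **Instantaneous amplitude**: magnitude of convolution with a 5-cycle
  complex Morlet wavelet (Gaussian SD σ_t = n_cycles/2πf, support ±3.5 σ_t),
  scaled so a unit-amplitude tone at f yields envelope 1.  Half a wavelet
  support at each edge is flagged invalid and excluded from all binned
  statistics downstream.
* **Decimation**: wide-band recordings (e.g. 24 414 Hz acquisition) are
  polyphase-resampled to 1000 Hz before phase/amplitude extraction; the
  analysis content lives below 300 Hz, and this cuts cost ~24×.  All
  synthetic tests run at 1000 Hz directly.

## Phase–amplitude coupling

Phases are binned every 18° (N = 20 bins); the amplitude series is averaged
per bin and the bin means are normalized to a distribution P.  With entropy
H = −Σ P log P (natural log) and H₀ = log N,

MI = (H₀ − H) / H₀.

MI is exactly 0 for uniform P and exactly 1 for a single-bin delta; values
are clamped against floating-point dust so the bounds hold exactly.  Two
renderings of the same quantity circulate in the literature — a difference
written as (H − H₀)/H₀ (which is ≤ 0) and a reference entropy written
log N²; since the index must lie in [0, 1] with 0 meaning no coupling, the
implementation uses (H₀ − H)/H₀ with H₀ = log N and offers
`reference="logN2"` as a selectable alternative (it compresses the scale,
mapping uniform to ½, but preserves ordering).

Empty phase bins (possible on short segments) contribute a bin mean of 0;
any distribution computed with fewer than 10 samples in some bin is flagged
low-confidence.  Comodulogram grids default to phase 4–7.5 Hz and amplitude
30–90 Hz in 0.5 Hz steps; a 2–20 Hz phase preset is provided for
exploratory figures.  Directionality: the phase channel is the upstream
channel; swapping phase and amplitude channels is a different computation
unless the channels coincide.

## Spike entrainment

The spike-phase distribution over the same 18° bins, normalized by total
spike count, feeds the identical MI formula.  Per-unit MI spectra are
computed over 4–90 Hz (0.5 Hz steps, f ± 0.5 Hz phase bands) and normalized
to their per-unit maximum; a population band is any maximal contiguous run
of frequencies at which more than 25% of units have normalized MI ≥ 0.8.
Both knobs are configurable — no principled criterion for "strongly
entrained" exists, so the defaults were chosen once to cleanly separate
slow- and gamma-locked subpopulations in the generator and are documented
rather than tuned.

Phase locking within an identified band: the LFP is band-passed, the
Hilbert phase is read at each spike by nearest-sample lookup (at ≥1 kHz the
lookup error is <2° for f ≤ 90 Hz), and the circular mean angle, resultant
length R and Rayleigh p are computed.  A unit is *entrained* iff the
Rayleigh test rejects uniformity at p < 0.05 **and** it has at least 30
spikes; the spike-count floor guards the small-sample validity of the
Rayleigh approximation, and units failing it are flagged so group angle
statistics exclude them.  Implantation stages bin weeks as acute (0–2),
early-chronic (3–8) and chronic (9–16).

## CSD depth alignment

The stimulus-locked LFP average (window −100 to +200 ms; events clipped by
recording edges are dropped and counted) is smoothed across sites and
differentiated twice along depth:

csd_i = −(V_{i−1} − 2 V_i + V_{i+1}) / Δz²,

so inward current sinks are negative; boundary channels are lost (no
Vaknin-style padding — the estimator is kept strictly local).  Smoothing
options: a [0.25, 0.5, 0.25] site kernel (default) or a 3-site moving local
line fit (equivalent to a 3-point moving average for equispaced sites);
edge channels are left unsmoothed so that a depth-affine, time-varying
common-mode offset still cancels exactly in the second difference.

L4 is anchored at the minimum CSD within 0–100 ms after stimulus onset.
Significance floor: the sink must undercut the *most negative pre-stimulus
baseline CSD value* by more than 3× the baseline SD.  The post-stimulus
window is a search over ~10³ (channel, time) cells, so the relevant chance
level is the extreme the same-sized baseline window already produces, not
3 SD of a single cell; a plain 3 SD floor would declare a "sink" in pure
noise nearly always.  If no significant sink exists the alignment is marked
failed.  Layers relative to the L4 channel: the two channels above are
L2/3, anything higher L1, the three channels below L5/6, and deeper sites
CA1 (also any site below 1000 µm when the geometry is known); the template
is configurable.

## Unit classification and yield

Trough-to-peak latency is measured from the global waveform minimum to the
largest subsequent maximum, with parabolic sub-sample interpolation — at
24 414 Hz the raw grid (0.041 ms) is coarse relative to the 0.41 ms
boundary, and interpolation shifts latencies by well under one sample.
Classification is a pure threshold: < 0.41 ms putative inhibitory,
≥ 0.41 ms putative excitatory (boundary inclusive to excitatory).  Yield
tables report counts and class fractions per region × week; a cell with
fewer than 3 units is flagged "insufficient detection" and should be
excluded from circular group statistics (configurable floor).

## Circular statistics

Degrees at the API, radians internally (single conversion point).

* **Rayleigh test**: Z = nR², p from the standard corrected series
  exp(−Z)·[1 + (2Z − Z²)/4n − (24Z − 132Z² + 76Z³ − 9Z⁴)/288n²],
  clipped into (0, 1].
* **Watson–Williams**: F test for equality of mean directions with the
  1 + 3/8κ̂ concentration correction (κ̂ by Fisher's A₁ inverse); groups
  with n < 10 or pooled resultant length < 0.45 are flagged as violating
  the guideline assumptions.  Applied to entrainment angles across
  implantation stages as independent unit-level samples — units contribute
  once per stage and animal identity is not modelled inside the test; this
  is the standard form of the test and the repeated-measures structure is
  instead honoured in the longitudinal mixed model.
* **Two-sample Kuiper**: V = D⁺ + D⁻ on the circular ECDFs (rotation
  invariant by construction), p from the asymptotic series with Stephens'
  finite-n factor on n_eff = n₁n₂/(n₁+n₂), truncated at terms < 1e−10.

Monte-Carlo calibration (seeded, in the test suite) places the type-I error
of Rayleigh, Watson–Williams and Kuiper within [0.03, 0.07] at α = 0.05.

## Longitudinal model

The evoked-vs-resting comparison fits

value ~ 1 + rcs(week) + condition + condition × rcs(week),  (1 | animal)

where rcs is the Harrell restricted cubic spline with 4 knots at the
5/35/65/95th percentiles of the pooled week variable (basis: week plus two
restricted cubic terms; exactly linear outside the boundary knots).  The
mixed model is fitted by maximum likelihood (statsmodels MixedLM; BFGS with
a Powell retry) so likelihood-ratio tests are valid; a singular fit falls
back to OLS with animal-clustered robust covariance and is flagged.  A
random intercept per animal is the minimal repeated-measures structure and
the default; random slopes are deliberately out of scope.

Two significance readouts are reported separately because they answer
different questions: an LR test comparing the full model against one with
no condition terms (main + interaction dropped; χ² with df = number of
dropped columns), and the per-week CI-overlap rule — week w is flagged only
if [fit ± 1.96 SE] of the two conditions are disjoint, with touching
intervals counting as overlap.  The SEs are marginal fitted-value SEs from
the fixed-effects covariance.  The CI-overlap rule is deliberately
conservative: even for independent fits with equal SEs it corresponds to a
pointwise z of 2 × 1.96/√2 ≈ 2.77, and because the two condition curves
share the baseline spline coefficients its realized null flag rate is far
below 0.05 (≈ 0 in 500-study simulations).  It should be read as a
high-specificity screen, not an α = 0.05 test.

Time-only effects use one-way ANOVA with Tukey HSD (statsmodels).

## Synthetic-session generator

The generator is first-class, tested code; its defaults are the study
conditions the analysis is validated under.

* **Coupled LFP**: x(t) = sin φ_low(t) + A(t) sin 2πf_amp t + ε,
  A(t) = a·[1 + χ cos(φ_low − φ_pref)]/(1 + χ), ε ~ N(0, σ²).
  Defaults: 5 Hz phase, 65 Hz amplitude, a = 0.5, σ = 0.5.  χ (modulation
  depth) is the ground-truth coupling strength: χ = 0 makes the envelope
  phase-independent, and the measured MI is monotone in χ.  This
  multiplicative-envelope construction is the minimal model whose
  ground-truth MI is controllable; it is not a biophysical LFP model.
* **Phase-locked spikes**: inhomogeneous Poisson by thinning with
  λ(t) ∝ exp(κ cos(φ_band(t) − φ_pref)), normalized so the realized rate
  approaches the target; κ = 0 gives uniform phases.  Thinning is exact for
  inhomogeneous Poisson and trivially verifiable.
* **Laminar sessions**: per-channel coupled background (independent noise),
  stimulus-locked sink at a chosen channel — Gaussian across depth
  (SD 0.8 channels), biphasic in time (sharp negative lobe at the set
  latency, 35% positive rebound) — with ≥10 stimuli recommended for a
  stable CSD average.
* **Waveforms**: trough-to-peak latencies from two Gaussians at 0.25 ms
  (narrow/inhibitory) and 0.54 ms (wide/excitatory), SD 0.04 ms, which puts
  the 0.41 ms boundary 4 SD from either mode so that <2% of mass crosses it
  and classification tests are deterministic in practice.
* **Longitudinal tables**: value = baseline(w) + effect(w)·1[evoked] +
  animal intercept + noise, for 8 animals × weeks 0–16 × 2 conditions,
  with MI-scale defaults (baseline 0.05, animal SD 0.01, residual SD 0.01).

Determinism: every generator consumes a `numpy.random.default_rng(seed)`
stream; identical seeds reproduce sessions bit-for-bit (continuous data are
float32 end-to-end, so bundle round-trips are lossless).

**What the generator does not emulate**: volume conduction and realistic
laminar LFP biophysics, non-Poisson spike-train structure (bursting,
refractory interactions beyond the detector lockout), gliosis-driven
impedance drift, non-stationarity within a session, and correlated noise
across channels.  Passing tests therefore establish estimator correctness
and calibration under the assumed statistical structure — not robustness to
every failure mode of real chronic recordings.

## Problem sizes used in validation

Validation simulations use 40–60 s signals at 1000 Hz, 40-stimulus sessions
for CSD recovery (100 seeded repetitions), 500–2000 Monte-Carlo replicates
for test calibration, and 20 seeds × 4 coupling strengths for the
monotonicity check; these sizes give stable Monte-Carlo estimates for the
quantities asserted while keeping the full suite fast.

## Known limitations

* The Hilbert-phase frequency resolution is set by the f ± 0.5 Hz analysis
  band; couplings narrower than the grid step cannot be resolved further.
* Entrainment spectra default to the evoked-condition recordings; condition
  is configurable but not jointly modelled.
* The Watson–Williams and Kuiper tests treat units as independent samples
  (see above); animals contributing many units inflate their weight.
* `identify_band` thresholds (0.8 normalized MI, 25% of units) are
  heuristics; report them alongside any band claims.
* No surrogate-based MI significance (phase-shuffled nulls) is included;
  the uncoupled noise floor from the generator serves that role in tests.
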