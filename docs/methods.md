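# Methods

## Model and likelihood

Spindle occurrences are modeled as a temporal point process with
conditional intensity λ(t|H_t), log-linear in sleep-stage indicators, the
cos/sin embedding of SO phase, stage×phase interactions, an optional
quadratic term in normalized SO power (SOP), optional SOP×phase
interactions, and a spline history term over the lag since the most
recent spindle. The likelihood is evaluated in discrete time: bins of
dt = 0.1 s carry binary counts, and the Poisson GLM with log link and
exposure dt approximates the continuous likelihood with error O(λ·dt).
With λ rarely above 0.5 events/s, λ·dt ≤ 0.05, so the binary-count
approximation is comfortably accurate while a full night stays at
~3×10⁵ bins. Two events in one bin are capped at one with a logged
warning.

Assumptions worth stating explicitly:

- **Renewal-style history.** The history term depends only on the time
  since the last event, not on deeper history. Runs of short intervals
  are therefore modeled through the chain of single-lag effects.
- **Stage-invariant history.** One history curve per recording; no
  stage×history interactions.
- **Causality.** History predictors for bin k use only events strictly
  before the bin start; covariates are evaluated at bin centers.

Fitting is Newton/IRLS on the exact Poisson log-likelihood (for the
canonical log link the two coincide), with step-halving, convergence at
relative log-likelihood change < 1e-10, and the coefficient covariance
taken as the inverse observed Fisher information at the MLE. Zero-
occupancy stage columns are dropped, as is any column that is linearly
dependent on the columns to its left (greedy rank filter, relative
tolerance 1e-8). This matters for the full stage-interaction model: a
design carrying both the global phase pair and all five stage×phase pairs
is rank-deficient by exactly two, and the filter removes the trailing
(Wake) pair, making Wake the reference stage. Stage-specific effective
phase pairs are then (β₁+β_{s,1}, β₂+β_{s,2}) with absent coefficients
read as zero.

## History basis

`g_k` are cardinal-spline interpolation weights (cubic Hermite segments,
tangent coefficient c = 0.5, i.e. Catmull–Rom; one-sided tangents at the
ends). The spline through control values {h_k} passes exactly through
(knot_k, h_k), the weights sum to one inside the knot span, and all
weights vanish beyond the last knot, so the modulation returns to exactly
1 at long lags. Default knots: dense over the short-term structure
{0, 0.5, …, 4, 5, 6.5, 8, 10, 12.5, 15} s (K = 15), with a long-term
extension {20, 30, 40, 50, 60, 75, 90} s (K = 22) covering the infraslow
range. The layout concentrates resolution where refractory/excitatory
structure lives and keeps the long-lag block cheap.

## Read-outs

- History modulation: m(τ) = exp(Σ h_k g_k(τ)); 95% CI as
  exp(linear ± 1.96·SE) with SE from the delta method on the h-block
  covariance. CIs are pointwise, not simultaneous — refractory and
  excitatory windows inherit that (documented) liberality.
- Features: refractory = length of the run from lag 0 with upper CI < 1;
  excitatory = longest run anywhere with lower CI > 1 (contiguity with
  the main peak is not required); peak = modulation maximum inside that
  run; crossings located by linear interpolation between grid points;
  empty windows give NaN. The infraslow multiplier is the trapezoidal
  mean of m(τ) over 40–70 s (1 for a null curve).
- Phase coupling: M = √(b₁²+b₂²), φ_pref = atan2(b₂, b₁) on the
  context-specific pair; angular CI by the delta method (not bootstrap);
  an arc ≥ 2π is reported as "no statistically relevant preferred phase",
  which is what near-empty stages (N1) produce. φ_pref-vs-SOP curves are
  unwrapped along the grid before the CI band is attached, then
  re-wrapped.
- Deviance decomposition: sequential fractions over a nested chain
  telescope to 100% of the null→full reduction; single-factor fractions
  (D_null − D_factor)/(D_null − D_full) are reported alongside, and the
  pipeline emits both the history-last and history-first orderings, since
  the attribution convention is a genuine free choice.
- Synergy: per-event information gains I_X = (LL_X − LL_null)/(n·ln 2)
  bits/event; index = (I_AB − I_A − I_B)/I_AB. This deviance-based form is
  zero exactly when the two factors' gains are additive, negative under
  redundancy; other normalizations exist, and only the zero point is
  interpreted.
- Goodness of fit: time-rescaling — τ_j = ∫λdt between consecutive events
  (cumulative hazard interpolated within bins), z_j = 1 − exp(−τ_j)
  against Uniform(0,1), with the 0.05-level criterion D < 1.36/√n.

## SO covariates from EEG

Phase: zero-phase FIR bandpass 0.4–1.5 Hz (~4 cycles of the low edge in
taps), analytic signal, angle — so phase 0 sits on band-limited maxima
(up-states), negative phase on the rising flank, range (−π, π]. SOP:
Hann-window band power 0.3–1.5 Hz in dB on 4-s windows, interpolated to
the model grid and normalized per recording by the 5th–95th percentile
range, clipped to [0, 1]. The percentile scheme is this package's own
robust, recording-relative choice; published SOP normalizations differ in
detail, so absolute SOP values should not be compared across pipelines.
The sigma-band envelope detector shipped here is demo plumbing only;
production event trains come from an upstream detector.

## Synthetic nights

The generator emulates what the model needs from a night of sleep, not
the EEG waveform: a 30-s-epoch Markov hypnogram (default transition
matrix with stationary occupancy ≈ 6/42/24/19/9 % for
N1/N2/N3/REM/Wake), an SO proxy A(t)·cos(2πf·t) with f = 0.85 Hz whose
amplitude follows sleep depth (deeper stage → larger slow waves; a
coupling knob blends in slow log-normal noise so stage and SOP correlate
imperfectly, as in real sleep), and an event train sampled per 0.05-s bin
with probability 1 − exp(−λ·dt). History in the generator defaults to the
same last-event spline as the fitted model — that makes the fitted model
exactly well-specified, which is what parameter-recovery testing needs —
with an additive multi-event mode (`history_mode="sum"`) available as a
robustness scenario. Sampling is exact, via exponential thresholds on the
cumulative hazard, and bit-reproducible under a seed.

The `paper_default` scenario encodes a healthy-sleeper regime: baseline
rates 11/5/1.5/0.5/0.5 events/min in N2/N3/N1/REM/Wake, phase-coupling
magnitude M = 0.22 with φ_pref = 0 in N2 shifting to −π/8 in N3, and
history control values calibrated once so the true curve crosses 1 at
1.8 s and peaks at 1.9× at 3.5 s (excitatory window ≈ 2.9 s). The
refractory floor is log-modulation −2.8 (m ≈ 0.06) rather than a hard
zero: a literal zero floor would yield recordings with no refractory-lag
events at all and a divergent (separated) MLE, whereas a soft floor keeps
the likelihood regular while remaining "close to 0" on the modulation
scale. An 8-h night yields ≈ 3,000–3,300 events.

What the generator does **not** emulate — and what recovery tests
therefore cannot vouch for: spindle morphology (duration/amplitude/
frequency), detector noise (missed or spurious events, the "skipped-event"
echo peak near twice the peak lag), artifacts and stage-scoring errors,
non-stationarity across the night beyond stage/SOP, and deep-history
effects beyond the last event.

## Numerical choices and degenerate inputs

- Bin width 0.1 s for fitting, 0.05 s for simulation; event times are
  kept exact (not quantized) for history lags.
- CI level 95% everywhere; Z = 1.959964.
- Bonferroni across the four history features in feature panels; Welch
  (unequal-variance) t-tests.
- Global permutation statistic: max over lags of |Welch t|; global
  p = (1 + #{perm ≥ obs})/(n_perm + 1); pointwise mask at the null
  max-statistic's 95th percentile. The max-|t| choice controls the
  family-wise rate without smoothness assumptions; an area statistic
  would weight broad weak differences more.
- Watson–Williams from the classical high-concentration F approximation
  with the 1 + 3/(8κ̂) correction; warns below κ̂ = 1 or n < 5 per group.
- Degenerate inputs: empty trains refuse to fit; < 10 events refuse the
  KS test; zero-variance curves refuse correlations; empty feature
  windows give NaN; vacuous stages give "no preferred phase" rather than
  a misleading angle.

## Study sizes

The test suite and `scripts/acceptance.py` run their studies at sizes
chosen to make Monte-Carlo error small relative to the tolerances being
checked: 100 nights (tests) / 30 nights (acceptance script) for
coefficient-recovery coverage, 200 runs for KS calibration, 400–500
small-recording replicates for χ² calibration, 20/10 nights for the
synergy population, 1,000/300–500 replicates for the circular- and
permutation-test calibrations. Coverage is assessed pooled over
coefficient×replicate pairs (with a per-coefficient floor), the scale at
which a 95% nominal level is statistically meaningful at these replicate
counts.

## Known limitations

- The renewal (last-event) history is a modeling choice; bursty trains
  whose rate depends on multiple recent events are only approximated, and
  the `sum`-mode generator exists precisely to probe that mismatch.
- Pointwise CIs make the refractory/excitatory windows mildly liberal as
  detection calls, and the CI-based excitatory length is conservative
  (shorter) relative to the true m > 1 window at single-night sample
  sizes.
- The SOP normalization is recording-relative; cross-recording SOP values
  are comparable only in rank, not in dB.
- No regularized or Bayesian fitting; near-separated designs (e.g. a
  stage with events but almost no occupancy) fail loudly instead.
- Delta-method angular CIs degrade for very small coupling magnitudes;
  such contexts are flagged as having no preferred phase.
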