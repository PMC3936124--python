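# Methods

This note documents the models behind `pvtsim`, the parameter choices that
matter, what the synthetic data do and do not emulate, and the numerical
conventions the tests rely on.

## Protocol engine

The session executor runs on a continuous virtual clock (real-valued
seconds; no wall-clock arithmetic anywhere inside the engine). One trial
cycle is ISI → stimulus → response → 500-ms feedback. Conventions:

- **Session end.** A new ISI starts only while the clock is strictly below
  `session_duration_s`, and a stimulus whose onset would fall past the
  duration is not shown; a stimulus shown in time runs to completion (response
  or 65-s timeout) past the nominal duration. Consequently every recorded
  event lies within `[0, session_duration_s + no_response_timeout_s]` and a
  zero-duration session has exactly zero trials.
- **False starts** abort the pending ISI and draw a fresh one by default
  (`false_start_redraws_isi=False` resumes the remainder instead — the
  historical hardware behaviour is not documented, so both are supported).
  The feedback interval is charged after false starts as well as after valid
  responses.
- **Classification** is strict: false start if the response precedes the
  stimulus, no-response if the response lags the stimulus by more than 65 s,
  valid otherwise. Lapse thresholds are likewise strict (`RT > 500 ms`).
- **Determinism.** All randomness flows through one `numpy` generator seeded
  per session; the seed is stored in the session and its file. Identical
  seeds and parameters give byte-identical session files.
- Recorded and true RTs are stored at 0.1-ms resolution, matching
  sub-millisecond event timestamping; times within the engine stay at full
  float precision.

The ISI draw is uniform on the closed interval `[isi_min, isi_max]`
(endpoint inclusion is a measure-zero distinction, fixed for test
determinism). The default major-lapse threshold is 3000 ms; it is an
analysis parameter, not part of the task definition, and fully configurable.

## Device delay chain

`recorded = poll_quantize(onset + true RT) + fixed_latency + |N(0, σ_j)| − onset`.

- The stimulus appears at the next monitor refresh tick; the onset
  *timestamp* is taken at that tick (emulating software that tracks the
  refresh cycle), so refresh quantization shifts events but contributes no
  residual to the recorded RT. The closed-form mean delay is therefore
  `poll_period/2 + fixed_latency + σ_j·√(2/π)` exactly.
- Poll and refresh phases are redrawn uniformly per trial by default
  (free-running clock domains); fixed-phase mode exists for exact unit
  tests.
- Jitter is half-normal (a zero-mean Gaussian truncated at zero extra
  delay): hardware delays never make a response appear *earlier* than it
  occurred. With σ_j the pre-truncation SD, the mean contribution is
  σ_j·√(2/π) and the variance σ_j²(1 − 2/π).
- Tick quantization rounds `(t − phase)/period` to 9 decimals before the
  ceiling so that on-tick inputs are fixed points (idempotence) despite
  float noise; the slack is sub-nanosecond and physically irrelevant.

**Presets.** `reference` has infinite rates and zero latency/jitter — it
records true RTs exactly and plays the role of the external RT-box ground
truth. `gaming` (1000-Hz poll, 6.1-ms latency, 1.5-ms jitter SD) has a
closed-form mean delay of 7.8 ms; `standard` (125-Hz poll, 27-ms latency,
2.5-ms jitter SD) of 33.0 ms. The latencies were chosen once so the totals
fall inside the published closed-loop measurement ranges for real gaming
(~5–10 ms) and standard-mouse (~31–36 ms) configurations, encoding the
finding that poll rate alone (a 3.5-ms mean-delay difference) does not
explain the standard mouse's excess — the remainder (click-detection logic,
driver path) is lumped into `fixed_latency_ms`.

## Synthetic subject

The two-process alertness model is expressed directly as a latent RT deficit
in milliseconds:

`deficit(t, c) = max(0, G·(1 − e^(−t/τ)) + A·cos(2π(c − φ)/24))`.

The published group-average model that operational prediction tools fit is
not printed anywhere accessible to this package; this standard
saturating-exponential + single-harmonic form is a documented stand-in, not
a reproduction. Defaults (chosen once, as field-plausible): τ = 16 h
(homeostatic build-up), G = 120 ms (asymptotic homeostatic RT penalty),
A = 40 ms, φ = 05:00 (circadian trough). The floor at zero keeps the deficit
a physical quantity; it preserves monotonicity in time awake at fixed phase.

Valid RTs are lognormal, *moment-matched* so that `baseline_mu_ms` and
`baseline_sigma_ms` are the exact mean and SD at zero deficit; the deficit
shifts the mean. A lapse mixture with probability
`clip(p₀ + g·deficit/1000, 0, 1)` replaces the draw by
`500 ms + Exp(300 ms + deficit)`. False starts are a Poisson process over
the ISI with a deficit-independent rate.

The `satiated` preset is calibrated to the rested human anchor — mean 240 ms,
SD 29 ms — with `p₀ = 0`: that anchor describes baseline intrasubject
variability, and any non-trivial lapse mixture is incompatible with a 29-ms
SD around a 240-ms mean, so rested lapses arise only from the (thin)
lognormal tail and lapse probability grows with sleep pressure. The
`tsd85h` preset shares the physiology and enables lapse coupling
(`p₀ = 0.01, g = 2`) and false starts (0.01 s⁻¹) for deprivation studies.

**What the generator does not emulate:** time-on-task effects within a
session, sleep inertia, napping/recovery sleep, inter-subject parameter
heterogeneity beyond what a test draws explicitly, and motivational or
practice effects. Tests passing on these synthetic subjects certify the
pipeline's arithmetic and statistical behaviour, not human validity.

## Session statistics

Computed on recorded (device) RTs by default — what a real platform
measures — with a `use_true_rts` switch for oracle studies. False starts and
no-responses are counted but excluded from all RT-based statistics. Speed is
the mean reciprocal RT in s⁻¹ (the field's standard transform; the name
alone does not fix a formula). Tail means use `k = ceil(0.1·n)` without
interpolation. With zero valid trials the RT fields are NaN and counts are
still reported.

The RT-divergence statistic's published definition is external to this
package; the implemented surrogate is the base-2 Jensen–Shannon divergence
between histograms on 20-ms bins over [100, 1000] ms with under/overflow
bins — symmetric, zero iff the histograms coincide, and 1 for disjoint
supports. It is clearly labelled and isolated so a different definition can
be swapped in.

## Individualized prediction

The predicted statistic is modelled as `y = θ·x(t, c) + ε`,
`x = [1, 1 − e^(−t/τ̄), cos(2πc/24), sin(2πc/24)]`, with τ̄ frozen at the
group value (16 h) and `ε ~ N(0, σ²)`. Freezing the nonlinear time constant
makes the update conjugate: closed-form, order-independent (batch equals
incremental), and numerically trivial at 4 parameters. The cos/sin pair
lets the circadian *phase* be learned implicitly even though the basis is
linear. The default statistic is `sqrt(minor lapses)` (variance-stabilizing
for counts); `mean_rt` is also supported.

The shipped prior (`θ̄ = [1, 4, 0, 0]`, `Σ = diag(1, 4, 1, 1)`, `σ² = 0.2`
on the sqrt-lapse scale) encodes roughly one rested lapse per session rising
to ~25 under full pressure, with broad uncertainty. `prior_weight =
trace(Σ_post)/trace(Σ_prior)` is 1 before any data and non-increasing in the
number of sessions — a theorem under conjugacy, which the tests exploit.
Forecast intervals are central normal posterior-predictive intervals;
horizons beyond 24 h are refused without an explicit override, since
individualized models of this family are only validated up to a day ahead.

Calibration checks (95 % interval coverage on 500 held-out sessions;
posterior-mean recovery within 3 posterior SDs after a 43-session 85-h
deprivation schedule) are run *within* the linearized Gaussian observation
model — conjugate self-consistency. The full RT pipeline (sessions →
statistics → posterior → forecast) feeds the post-hoc trail and
learning-curve tests, where the generative model is deliberately mismatched
to the linear basis; there the claim tested is only that individualization
reduces prediction error, not exact coverage.

## Closed-loop validation

The simulated operator emits log-uniform true RTs on [160, 2000] ms (dense
at the fast end, still reaching the slow end), no false starts, no lapses.
Five 5-min sessions per device give on the order of 210 paired RTs, the
count emerging from the protocol engine rather than being fixed.
Bland–Altman limits use the sample SD (n−1); at n ≈ 211 the sample vs
population distinction is far below the 0.1-ms reporting resolution. The
delay table reports per-device min/mean/max/SD sorted ascending by mean,
with SD 0 by convention for a single pair. Cross-configuration means are
unweighted means of per-device means, reported at 0.1-ms rounding.

## Problem sizes

Defaults throughout were chosen as the study conditions themselves: 5- or
10-min sessions, five-session closed-loop runs, 85-h/2-h deprivation
schedules (43 sessions), 10⁴-draw calibration samples, 200-seed envelope
checks, 500-replicate coverage runs. The whole test suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

- The two-process stand-in and the lapse coupling are plausible but not
  fitted to any dataset; absolute lapse counts should not be interpreted.
- The delay chain abstracts USB/OS behaviour as quantize + latency + jitter;
  it does not model LCD pixel response, bus contention, or driver
  scheduling.
- The prediction model's homeostatic feature saturates by ~48 h awake, so
  very long deprivation mostly informs the circadian pair and intercept.
- The PVT-192-compatible binary session format is not implemented (the
  format is proprietary/undocumented); sessions persist in this package's
  documented text format plus CSV exports.
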