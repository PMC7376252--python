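# Methods

## The model

rhythmkit fits the single-component, fixed-period cosinor model

```
y_ij = M + A·cos(2π(t_j − φ)/T) + ε_ij,   ε_ij ~ N(0, σ²) i.i.d.
```

to one feature under one condition, where `t_j` are the sampled zeitgeber
times, `M` is the MESOR (rhythm-adjusted mean), `A ≥ 0` the amplitude,
`φ` the acrophase and `T` the period.

**Fixed period.** `T` defaults to 24 h and is never estimated. The target
design samples only four distinct clock times 6 h apart; a free period is
unidentifiable there, and entrained animals under a 12:12 light/dark cycle
are by construction on a 24 h cycle.

**Estimation.** With `T` fixed the model is linear in the
reparameterization `y = M + β·cos(ωt) + γ·sin(ωt)` (`ω = 2π/T`), so
`linearized_fit` solves it exactly by ordinary least squares and maps back
via `A = √(β² + γ²)`, `φ = (T/2π)·atan2(γ, β)`. `fit_cosinor` additionally
runs a Levenberg–Marquardt polish on `(M, A, φ)`; because the closed form
is already the global optimum, the polished solution is adopted only if it
lowers the SSE beyond round-off, which keeps the two routes identical to
well below 1e-8 and makes the closed form a built-in correctness check on
the nonlinear path.

**Canonical parameters.** A negative fitted amplitude is folded to
`A > 0` by a half-period phase shift; `φ` is wrapped to `[0, T)`. When
`A` is numerically zero (below 1e-12 of the data scale) the phase is
meaningless and is reported as `0.0` with an explicit
`phase_defined=False` flag rather than an arbitrary angle. The acrophase
convention is *clock time of the fitted peak* in hours (so "acrophase
ZT8" means the curve peaks 8 h after lights-on), not the traditional
negative-radians cosinor angle — this matches how diurnal studies report
phases.

**Estimability.** A series is fittable when it has ≥ 4 observations at
≥ 3 distinct time points modulo the period. Anything less — including a
series more than half of which is missing (e.g. below a detection floor)
— yields the call `nd` (not detected) with NaN parameters; such features
stay in every report table rather than being dropped.

## Rhythmicity: the zero-amplitude test

Rhythmicity is tested by the classical nested-model comparison of the
cosinor against the constant-mean model:

```
F = ((SSE₀ − SSE)/2) / (SSE/(n − 3)),   p = P(F(2, n−3) ≥ F)
```

The call is `rhythmic` when `p < α` (strict, default α = 0.05), otherwise
`nsr`. Degenerate cases: a perfect fit (SSE = 0) gives p = 0; a constant
series (SSE₀ = 0) gives p = 1 — a flat line carries no evidence of rhythm.
The test's type-I error at the 4 × 4 design is verified by simulation in
the acceptance suite (2,000 null studies; observed ≈ 0.05).

## Bootstrap confidence intervals

Parameter uncertainty comes from the bootstrap, vectorized across draws
(the schemes below never change the design matrix, so every refit is one
closed-form OLS solve):

- **Stratified case resampling** (default): replicates are resampled with
  replacement *within* each time point, preserving the fixed-ZT design.
  Because the empirical distribution of a stratum of `n_j` values has
  variance `(n_j−1)/n_j` times the unbiased sample variance — a material
  narrowing when `n_j` is 3–6 — centered stratum values are inflated by
  `√(n_j/(n_j−1))` before resampling. Noise-free strata are unaffected
  (all deviations are zero). Without this correction the null comparison
  false-flag rate measured ≈ 13–15% at a nominal 5%; with it, 6.5–8%.
- **Residual resampling**: residuals of the point fit, rescaled by
  `√(n/(n−3))` for the same reason, resampled globally and added back to
  the fitted curve. Useful when strata of 3 make case resampling coarse.

Both schemes keep every resample estimable by construction, so the
redraw-on-degeneracy counter the API exposes is structurally zero; it is
reported in the run manifest regardless.

Intervals are **percentile intervals** (default 95%, `B = 1000` draws,
minimum 200). BCa was considered and rejected: with strata of 3–6 the
acceleration estimate is unstable. The acrophase is treated circularly
throughout: draws live on `[0, T)`, the interval is a percentile interval
of signed deviations about the circular mean of the draws, and therefore
handles profiles peaking near midnight (draws at 23.5 h and 0.5 h average
to ZT0, not ZT12).

## Comparing two conditions

`compare_conditions` pairs draw `i` of one condition with draw `i` of the
other (independent streams) to form bootstrap distributions of

- ΔM (difference of MESORs),
- amplitude ratio `A₁/A₂`,
- Δφ, the circular phase difference wrapped to `(−T/2, T/2]`.

A contrast is **significant** when its CI excludes the null value (0, 1,
and 0 respectively). This difference-CI criterion is the default because
it is better calibrated and more powerful than declaring significance only
when the two per-condition CIs fail to overlap; the overlap heuristic is a
common convention in the field, so an `overlap` mode reproduces it for
comparability. Phase and amplitude contrasts are computed only when both
conditions are rhythmic — a phase of a non-rhythm is meaningless — while
the MESOR contrast is always available.

**Rhythm-change classification** combines the two rhythm calls with the
significance flags: `gained` / `lost` when rhythmicity appears or
disappears in the contrast condition; for two rhythmic profiles, exactly
one significant contrast gives `phase_shifted`, `amplitude_modulated` or
`mesor_shifted`, several give `compound`, none gives `unchanged`; two
non-rhythmic profiles are `both_arrhythmic`; an `nd` on either side
propagates to `indeterminate`.

## qPCR normalization

`delta_delta_ct` implements the comparative-threshold-cycle method with
amplification efficiency fixed at 2: per sample
`ΔCt = Ct_target − Ct_reference`; `ΔΔCt` subtracts the **arithmetic mean
ΔCt of the baseline group** of the same feature (the canonical Livak
formulation — equivalently, the geometric mean of baseline expression is
exactly 1); expression is `2^(−ΔΔCt)`. Whether the original convention
baselines to the group mean or to a single calibrator sample is generally
ambiguous in published legends; the group mean is assumed here. Records
missing either Ct are rejected and logged by sample id; an empty baseline
group is a hard error. `rescale_relative` divides by the baseline-group
arithmetic mean on the expression scale and is idempotent.

## Group tests

`mann_whitney` computes U from midranks and dispatches on the data: exact
enumeration of all `C(n1+n2, n1)` assignments for untied samples up to
200,000 combinations (covering the 3–12 animals per group this package
targets), a seeded 10,000-resample permutation test for tied data, and
the tie-corrected normal approximation beyond the cap. Two-sided p-values
double the smaller tail, capped at 1. `significance_stars` renders the
usual strict thresholds (`*` < 0.05 … `****` < 0.0001, `ns` otherwise),
with a marker switch (`$`) for versus-indicated-group contrasts.

## The synthetic-study generator

`rhythmkit.synthetic` emulates the around-the-clock design end to end:
four zeitgeber times (3, 9, 15, 21 by default), per-condition replicate
counts drawn uniformly from an inclusive range (default 3–6, mirroring
"n = 3–4" control versus "n = 5–6" challenged reporting) from a
design-level stream shared across features — in a real study all features
are measured on the same animals. Measurement noise is additive Gaussian
on the reported scale by default, the implicit assumption of least-squares
cosinor; a multiplicative log-normal option exists for strictly positive
data. Values below an optional detection floor are emitted as missing to
exercise the `nd` pathway. Each feature has its own RNG stream sub-seeded
from the dataset seed and a stable hash of the feature id, so adding a
feature never perturbs another's values; a fixed config reproduces the
dataset byte for byte.

The raw Ct generator places the configured expression model on the cycle
scale (`ΔCt = offset − log₂(model)` plus Gaussian cycle noise against a
constant-mean reference gene), so 2^–ΔΔCt normalization recovers the
configured relative profile up to noise. A rhythmic reference gene is
allowed with a warning — normalizing to an oscillating reference is a
real-world failure mode worth simulating, not an input error.

**What the generator does not emulate:** biological covariance between
features (features are independent given the design), animal-level random
effects shared across time points, heteroscedasticity across ZTs
(per-time-point noise is exposed but defaults to constant — published
legends give no values to copy), outliers, or any tissue-level mechanism.
Passing benchmarks therefore demonstrate statistical correctness and
calibration at the intended design, not robustness to every pathology of
real qPCR data.

## Benchmark scenarios and problem sizes

`rhythmkit.studies` fixes the simulated study conditions used by the test
and acceptance suites. Effect sizes default to amplitude twice the noise
SD — a clearly rhythmic but realistically noisy profile: a 3 h phase
advance (control peak ZT20 → challenge ZT17), a twofold amplitude change,
de novo gain and loss of rhythm, and a six-feature study covering the
whole change taxonomy at low noise (SD 0.3, 6 replicates per time point).
Monte-Carlo sizes — 2,000 null studies for the type-I error, 300 for CI
coverage, 200 per recovery scenario, B = 300–1,000 bootstrap draws — were
chosen so each experiment estimates its rate to within a couple of
percentage points while the whole benchmark completes in seconds.

## Numerical choices and edge cases

- Time points are compared modulo the period with a 1e-9·T tolerance when
  counting distinct design points.
- `sse_full` is clamped to `sse_mesor_only` to absorb round-off on
  near-constant series before the F test.
- Amplitude draws are non-negative by construction (`hypot`), so no draw
  canonicalization is ever lost in the bootstrap.
- Percentile CIs use linear interpolation of order statistics
  (`numpy.percentile` defaults).
- Ties in the grid-search oracle used by the tests resolve to the lowest
  acrophase, which matters only on the A = 0 ridge where every phase is a
  minimizer.
- Seeds: every stochastic routine takes an explicit seed; composite
  routines derive per-series seeds from the run seed plus a stable SHA-256
  hash of the series identity, so results are independent of dictionary
  or file order.

## Known limitations

- Single-component cosinor only: no harmonics, no period scanning
  (Lomb–Scargle, JTK_CYCLE, RAIN are out of scope), no mixed-effects
  cosinor for shared-animal designs.
- The zero-amplitude F test assumes i.i.d. Gaussian errors; with 3–6
  replicates per time point its calibration is verified by simulation but
  heavy-tailed noise will inflate the false-positive rate.
- Percentile bootstrap CIs at these sample sizes are mildly
  anti-conservative even after the small-stratum correction (null
  comparison flags fire at ≈ 7% for a nominal 5%).
- Two-condition comparisons only; multi-condition joint modelling and
  multiple-testing correction across features are deliberately left to
  the caller.
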