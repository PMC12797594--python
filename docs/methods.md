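# Methods notes

This note records the statistical models implemented in `circastat`, the
defaults that matter, the design choices made where the design was open,
and what the simulation benchmark does and does not demonstrate.

## Detection methods

### Cosinor regression

The single-component cosinor linearizes a cosine of known period P:
y = M + β₁cos(ωt) + β₂sin(ωt) + ε, ω = 2π/P, fitted by OLS. Rhythmicity is
the overall F-test of β₁ = β₂ = 0 with df (2, n−3); amplitude is
√(β₁² + β₂²) and acrophase the time at which the fitted cosine peaks,
reduced to [0, P). Assumptions: additive, homoscedastic, serially
independent noise; a single sinusoidal component. At least 4 points are
required (3 parameters + 1 residual df). A design matrix made singular by
period-aliased sampling raises an error rather than returning a pseudo-fit.
Perfect fits (residual sum of squares at rounding level) are reported with
p = 0 rather than an unstable F ratio.

### Rank-based scans (cosine-Kendall, JTK, harmonic-cosinor)

All three compare the ranked data against a library of discrete reference
waveforms and use Kendall's τ (tau-b) for both similarity and significance.
Consequences of ranking: verdicts are invariant under strictly monotone
transforms of the data, robust to outliers (one moved point flips at most
n−1 of the n(n−1)/2 pairs), and independent of the data's measurement
scale. Templates are evaluated pointwise at the observed times, so regular
and irregular sampling are treated identically.

Significance of τ: for n ≤ 12 with neither sequence tied, the exact null of
the concordance statistic S is computed by the inversion-count (Mahonian)
recursion; otherwise a normal approximation with the standard tie-corrected
variance and a ±1 continuity correction. Constant inputs are degenerate
(τ = 0, p = 1, flagged). The JTK and harmonic scans test |τ| two-sided —
a trough-aligned template is as informative as a peak-aligned one — and for
a discordant (negative-τ) winner the reported acrophase is the peak of the
sign-flipped template, not the raw template lag, so that "acrophase" always
means peak time.

Per-series multiple testing over the period × lag (× shape) grid uses
Bonferroni (ADJ.P = m·p capped at 1). Across many series, `batch_adjust`
offers Benjamini–Hochberg q-values (BH.Q) over the series' minimum raw
p-values, Bonferroni-only, or an automatic switch (BH at ≥ 20 series). The
within-series Bonferroni is conservative because grid templates are highly
correlated; this is the standard JTK-style trade-off and is what keeps the
false positive rate of the scans near zero in the benchmark.

Amplitude for rank methods has no model-based estimator; we report half the
difference between the means of the top and bottom deciles of the data, a
robust range proxy chosen over max−min (outlier-sensitive) and over the
least-squares template scale (which would reintroduce the non-robustness
that ranking removed).

### Default grids

- periods: 20–28 h in 0.5-h steps (the circadian band; half-hour resolution
  matches the granularity at which period estimates are reported);
- lags: multiples of the series' median sampling interval (floored at 1 h)
  covering one period, matching template discreteness;
- JTK asymmetries (rise fractions): {0.2, 0.35, 0.5, 0.65, 0.8} — symmetric
  plus moderate and strong asymmetry at modest Bonferroni cost;
- harmonic weights γ: {0, 0.5, 1} with second-harmonic lag offsets
  {0, P/8, P/4} relative to lag₁; γ = 0 collapses to a plain cosine and is
  included exactly once per (period, lag₁) so the unimodal case is in the
  library without duplicated tests.

All grids are user-overridable; restricting them shrinks the Bonferroni
factor without changing any raw p.

### AR(1) noise correction

Serial correlation mimics slow rhythm and inflates false positives.
Detection operates on the residuals of the least-squares-scaled winning
template — not on the raw data, whose rhythm itself is autocorrelated. The
lag-1 residual autocorrelation r₁ is compared with the two-sided normal
null threshold z₀.₉₇₅/√n (α = 0.05); φ is the Yule–Walker estimate
(φ̂ = r₁). When detected, the series is filtered (y′ₜ = yₜ − φ̂yₜ₋₁,
dropping the first point) and the scan re-run; a sinusoid passes the filter
as a sinusoid of the same frequency, so rhythm content survives. The order
is fixed at 1; order selection (AIC) is an extension point. Regular
sampling (constant interval within 1%) is required — continuous-time AR
models for irregular series are out of scope, and the error message directs
users to the plain rank scans.

## Synthetic data and the benchmark

`table1_specs(seed)` builds four dataset classes, all 48 h at 1-h sampling
(48 points, the field's conventional resolution for two-day recordings):

| class          | groups | period | amplitude (log-uniform) | noise (% of A) |
|----------------|-------:|-------:|-------------------------|----------------|
| pseudo-random  |     50 |      — | —                       | —              |
| cosine         |     80 |   24 h | 0.001–10000             | 20–40%         |
| triangle       |     40 |   24 h | 0.015–10000             | 30–40%         |
| bimodal        |     32 |   24 h | 0.015–10000             | 20%            |

Amplitudes are drawn log-uniformly because the ranges span six to seven
decades. Noise is additive, uniform on [−cA, +cA] with c the per-group
noise fraction — symmetric and amplitude-proportional, so the
signal-to-noise ratio is amplitude-free by construction. Phases are uniform
over the period. Triangle groups draw their rise fraction uniformly from
[0.15, 0.45]; bimodal groups draw γ uniformly from [0.5, 1] and the
second-harmonic lag offset uniformly from [0, 6] h (0 to P/4). The
pseudo-random class is iid uniform noise. Each class derives its own
sub-seed from the master seed; generation is bit-reproducible.

What the generator emulates: two-day recordings with stable period, stable
phase, and stationary amplitude-proportional noise. What it does not:
damped or drifting oscillations, non-stationary variance, missing-data
patterns, count-valued or heavily skewed measurements, within-group
replicate structure (one series per group, as the benchmark design reports
per-group fractions). Passing the benchmark therefore shows correct method
behavior under clean stationary rhythms, not performance on every real
recording.

`run_benchmark` analyzes every generated series with each requested method
at default grids and α = 0.05 on the within-series ADJ.P, and reports
detection counts, the false positive rate on the pseudo-random class, and
the range of |PER − 24| over detected rhythmic groups.

Observed behavior at benchmark scale: all four methods hold the false
positive rate at or near 0/50 (Bonferroni over a correlated grid is
conservative); cosine, triangle and bimodal classes are detected at 100% by
every method, because with 48 points and noise bounded by 40% of amplitude
every waveform here retains a dominant fundamental component — shape
specificity shows up in period accuracy and in τ magnitude rather than in
detection counts. Period estimates concentrate on 24 h with a tail of
half-hour to 1.5-h deviations for the rank scans; these come from the
mismatch between continuously drawn shape parameters and the discrete
template library, which lets a neighbouring candidate period trade phase
drift across the two observed cycles against shape misfit.

## Numerical choices

- Ties broken deterministically everywhere: cosinor scan ties go to the
  smallest period; rank scans prefer (smaller p, larger τ or |τ|, smaller
  period, smaller lag, asymmetry nearest 0.5).
- `harmonic_reference` with γ = 0 evaluates the identical floating-point
  expression as `cosine_reference`, so grid-superset relations hold exactly.
- Template banks (pairwise sign tensors and tie statistics) are cached per
  (grid, time-grid), making many-series scans a single tensor contraction
  per series; the vectorized path is tested to agree with the scalar
  Kendall test to 1e-12.
- CSV values round-trip at better than 6 significant digits; unset BH.Q
  fields are empty cells. Duplicate time points are rejected, not averaged;
  missing cells are dropped pairwise per series.
- The exact Kendall null uses Python integers (no overflow); the normal
  branch guards zero variance (degenerate tie structures) by returning
  p = 1.

## Known limitations

- No population-mean cosinor with confidence ellipses; no detrending beyond
  the mesor term.
- AR correction is first-order and needs regular sampling.
- The harmonic library stops at two components; free-frequency second
  components are not modelled.
- Bonferroni over large template grids is conservative; power at very small
  n or very high noise is correspondingly reduced.
- Actogram binning uses the native sampling interval with per-figure
  normalization; no smoothing or rebinning options.
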