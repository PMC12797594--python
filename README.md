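# circastat

Circadian rhythm detection and visualization for time-series measurements —
behavior, physiology, or omics profiles sampled over days. `circastat` is a
headless library plus CLI for chronobiologists who need to decide, per
sample or per group, *is this series rhythmic, with what period, amplitude
and peak time?*

## Methods

Four detection methods share one result format (PER, AMP, acrophase, raw p,
within-series Bonferroni ADJ.P, across-series Benjamini–Hochberg BH.Q):

- **Cosinor** — ordinary least squares on the linearized cosine model
  *y = M + β₁cos(ωt) + β₂sin(ωt) + ε* with ω = 2π/P; rhythmicity is the
  F-test of β₁ = β₂ = 0 with df (2, n−3); AMP = √(β₁²+β₂²), acrophase is
  the fitted peak time. The fit is scanned over candidate periods
  (default 20–28 h, 0.5-h step) and the minimum p is Bonferroni-adjusted.
- **Cosine-Kendall** — nonparametric cosine concordance: the data are
  ranked against phase-shifted cosine references on a period × lag grid and
  scored with Kendall's τ (tau-b), making the verdict outlier-robust and
  invariant to monotone transforms.
- **Python-style JTK** — a JTK_CYCLE-type test using a library of symmetric
  and asymmetric triangle templates over a period × lag × asymmetry grid,
  with Kendall's τ supplying both the similarity score and the significance
  (exact inversion-count null for small untied samples, tie-corrected
  normal approximation otherwise). Templates are evaluated pointwise, so
  irregular sampling works out of the box.
- **Harmonic-Cosinor** — bimodal rhythm detection against two-component
  composites cos(2π(t−lag₁)/P) + γ·cos(4π(t−lag₂)/P), again scored by
  Kendall's τ; a two-component OLS fit backs the plotted overlay.

An **AR-corrected JTK** path estimates AR(1) noise (Yule–Walker on the
best-template residuals), tests its lag-1 autocorrelation against the
normal null, and — only when detected — pre-whitens
(y′ₜ = yₜ − φ̂·yₜ₋₁) and re-runs the scan.

The package also ships the grouped-CSV input dialect (a `Time` index column
plus one column per sample; identical labels form groups across up to three
files), chronobiology figures (shaded previews, double-plotted actograms,
best-fit overlays), and a simulation benchmark that regenerates the
four-class method-evaluation study (pseudo-random / cosine / asymmetric
triangle / bimodal).

## Worked example

```python
import numpy as np
import circastat as cs

rng = np.random.default_rng(42)
t = np.arange(48.0)                                   # 48 h, hourly
y = 10 + 3 * np.cos(2 * np.pi * (t - 8) / 24) + rng.normal(0, 1.0, 48)
ts = cs.TimeSeries(t, y, label="fly_1")

res = cs.PythonJTK(ts).fit()
print(res.summary())
```

```
========================================
Rhythm scan results: jtk
========================================
label             fly_1
method            jtk
n obs             48
PER (h)           24
AMP               3.37198
acrophase (h)     8
p (raw)           2.752e-14
ADJ.P             5.668e-11
BH.Q              -
tests in scan     2060
tau               0.7678
winning template  triangle P=24 lag=8 a=0.5
========================================
```

The scan recovers the generating 24-h period and the 8-h peak time; the raw
minimum p over the 2060-template grid stays overwhelming after Bonferroni
adjustment (ADJ.P ≈ 5.7·10⁻¹¹), so the series is called rhythmic. The
robust amplitude estimate (half the top-to-bottom decile spread, 3.37) sits
near the true value 3. `cs.Cosinor(ts).fit()` on the same data returns
MESOR 10.12, AMP 2.99 and acrophase 8.35 h from the parametric fit.

The same workflow from the shell:

```bash
circastat analyze data.csv --method jtk --out results.csv
circastat plot actogram data.csv --col fly_1 --out actogram.png
```

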