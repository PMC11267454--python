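# Methods

This note describes the models behind `polypgrowth`, the default
parameters and how they were calibrated, and known limitations. All
numerical statements about recovery and error rates here are the ones
checked by the test suite and the `analysis/` scripts on the package's own
synthetic data.

## 1. Synthetic cohort generator

Each individual *i* follows piecewise-exponential body-area dynamics on the
natural-log scale:

```
log A_i(t) = log A_i(0) + Σ_p (r_p + ε_i) · overlap(t, phase p)
```

- `phase_schedule` — contiguous `(start_day, end_day, rate)` phases; rates
  are per-day natural-log slopes, positive for growth, negative for
  shrinkage.
- `ε_i ~ N(0, rate_heterogeneity_sd²)` — an individual rate offset drawn
  once and **kept across phases** (a persistently fast grower is also a
  persistently slow shrinker). Default 0.02 /d.
- `log A_i(0) ~ N(start_size_logmean, start_size_logsd²)` — default
  ln 0.5 mm² ± 0.4.
- Observations add i.i.d. measurement noise `N(0, noise_sd²)` on the log
  scale. Default `noise_sd = 0.1`, chosen so that pooled log–log fits on
  default cohorts reach R² around 0.8 rather than being unrealistically
  clean.
- Mortality: per-sampling-interval Bernoulli hazards per phase. A death is
  recorded as one terminal `alive = False` row with no size; later days
  have no rows for that individual.
- Seeding: one `SeedSequence` per cohort spawns one child stream per
  individual, so cohorts are reproducible and individuals independent.

**Morphometrics.** Width derives from area isometrically on the log scale,
`log w = log A / (b + 1)` with allometric exponent `b = 2` by default, and
length is `log L = b·log w + N(0, shape_noise_sd²)`. Placing the scatter on
length (not width) matters: noise on the regressor of a log–log fit
attenuates the estimated exponent (errors-in-variables), whereas noise on
the response leaves it unbiased. `shape_noise_sd = 0.79` was calibrated so
that the default cohort's length-vs-width fit has R² ≈ 0.8 while the
noiseless generator recovers the exponent 2 exactly.

**Presets.** Two *Nematostella*-like regimes run two feed/starve cycles
over 198 days sampled every 3 days (growth phases of 9 days, starvation
phases of 90 days; ad-libitum rates T_D 2.4 d / T_1/2 29 d then
T_D 4.5 d / T_1/2 37 d, restricted-feeding rates 3.0/21.9/3.1/34.2 d), and
two *Aiptasia*-like variants run a single 14-day growth + 56-day
starvation cycle (symbiotic T_D 3.0 d with very slow shrinkage T_1/2
100 d; aposymbiotic T_D 3.6 d, T_1/2 27.9 d). The 9-day growth-phase
length is a package design choice: with the preset rates it yields a
~13-fold size gain per feeding bout, matching the magnitude of plasticity
the package is meant to exercise.

## 2. Multi-phase changepoint model

Pooled log body areas are fit with a continuous piecewise-linear mean in
time using the hinge basis `[1, t, (t−c₁)₊, …, (t−c_{m−1})₊]`. Errors are
i.i.d. Gaussian; the MLE gives `σ² = SSE/n` and

```
log L = −(n/2)·(ln(2πσ²) + 1),   AIC = 2k − 2·log L
```

with `k = m slopes + (m−1) changepoints + intercept + σ` parameters for an
m-phase model.

**Search.** Candidate changepoints are the observed sampling days. The
Gram matrix over the full hinge basis of all candidates is precomputed
once; any subset model's normal equations are then a submatrix solve, so
the exhaustive search over all feasible changepoint combinations (each
segment needs ≥ 3 observations on ≥ 2 distinct days) is a batched
`np.linalg.solve` over stacked small systems. Ties in SSE resolve to the
earliest changepoint placement. For ≥ 5 phases (or very large candidate
grids) exhaustive enumeration is replaced by a free-intercept
segment-cost dynamic program, warm-started by nesting the (m−1)-phase
optimum, followed by coordinate descent on each changepoint; this
guarantees the reported log-likelihood is monotone in the phase count. The
tests verify the production search equals a brute-force oracle on grids up
to 40 days.

**Uncertainty.** Percentile bootstrap resampling whole individuals (not
rows), refitting with the selected phase count each time; 95% intervals
for slopes and changepoints. Slopes convert to times via
`T_D = ln 2 / slope` (growth) and `T_1/2 = ln 2 / |slope|` (shrinkage);
a slope CI spanning zero yields an infinite upper time bound.

## 3. Per-individual rates, scaling, survivorship

Within fixed phase windows each individual's log area is regressed on day
by OLS (minimum 3 points; shorter series are skipped with a warning). The
**size-dependence test** regresses these slopes on log starting size per
(phase, condition) stratum; the verdict is "independent" iff the 95% CI of
the coefficient contains zero. Note a structural property of the
generator: because ε_i persists across phases, an individual's size
*entering a later phase* genuinely carries information about its rate in
that phase, so independence is only expected — and only asserted — for the
first phase, where starting size and rate offset are drawn independently.

`variance_explained` reports the R² of slope ~ log size + phase +
condition. `allometry_fit` and `powerlaw_fit` are log–log OLS fits
(statsmodels) returning exponents with standard errors, R² and AIC; exact
collinearity between cell size and cell number is flagged rather than
fatal. `geometric_prediction` gives the analytic exponents for isometric
cell packing: a projected body area scales as `s¹·N^{2/3}` for an
area-like cell-size proxy and `s^{2/3}·N^{2/3}` for a volume-like one.
Survivorship uses the Kaplan–Meier product-limit estimator (lifelines)
with right-censoring at the last observation of each surviving individual.

## 4. Cytometry simulation and quantification

**Generator.** A configurable cell-cycle mixture: 2N DNA intensities
`N(dna_2n_mean, (cv·mean)²)`, 4N at exactly twice 2N, S as a uniform
bridge between the peaks. Forward scatter is an area-like size proxy
(`fsc_a = 100·d²` for diameter d in µm, lognormal scatter within each of
four size classes). EdU labelling fills its quota S-first, then G2/M, then
G1 (a pulse marks replicating cells first). Contaminants: debris (low
scatter), doublets (doubled DNA area, high DNA pulse width, low
area/height ratio), plus two bead types on a dedicated bead channel —
counting beads (bright band) and optional dissociation-loss beads (dim
band). Event order is shuffled; truth labels are retained per event.

**Gating.** A deterministic cascade replaces manual gate drawing: bead
exclusion → scatter-debris floor → FSC-A/FSC-H singlet ratio →
SSC-W ceiling → DNA pulse-width window → 2N–4N DNA envelope, with an event
count logged after every gate. On default truth-labelled samples the
cascade removes ≥ 98 % of doublets and debris while keeping ≥ 95 % of
cells (verified in the tests).

**Cell-cycle fractions.** The 2N peak is the dominant mode of a
kernel-density estimate restricted to the lower 60 % of the intensity
range; 4N is fixed at twice 2N. Peak widths use a MAD-based robust sd from
events within ±10 % of each peak (the uniform S bridge would inflate a
plain sd). Raw windows of ±z·sd (z = 2) bias G1 downward by about 2
percentage points because Gaussian tails spill into the S region; the
default estimator therefore solves the 3×3 expected-count system of the
Gaussian-peaks-plus-uniform-bridge model (tail deconvolution,
`tail_correct=True`), after which recovered fractions on 50 000-event
samples are within ±1.5 percentage points of truth across the presets
(typically ±0.2). `tail_correct=False` returns the raw window proportions.

**EdU, counting, sizes.** The EdU threshold is the 99.9th percentile of a
matched negative control, making the index invariant to any common affine
intensity transform and bounding the false-positive rate at ~0.1 %.
Absolute counts follow `cells = (cell events / bead events) × beads
added`; dissociation loss is corrected by dividing by the loss-bead
recovery fraction (recovery > 1 is flagged as anomalous). Cell-size bins
map diameter edges to FSC-A cutoffs by monotone log–log interpolation of a
bead ladder (2–15 µm); edges outside the ladder's hull raise unless
extrapolation is requested.

## 5. Pipeline and reproducibility

`run_pipeline` chains simulate → fit → rates (and/or the cytometry branch)
and writes the report bundle: rate, AIC and changepoint tables, the
per-individual slope table with size-dependence verdicts, a gating summary
and a run log with the package version and all stage seeds. One master
seed deterministically derives a named child seed per stage (CRC-32 of the
stage name mixed into a `SeedSequence`), so any stage can be rerun in
isolation and a fixed seed reproduces every file byte for byte.

## 6. Limitations

- The changepoint model assumes homoscedastic Gaussian errors on the log
  scale and places changepoints only on observed sampling days; the
  bootstrap treats individuals as exchangeable within a cohort.
- Pooled slopes are population averages; with per-individual rate spread
  they estimate the mean rate, and the size-dependence test in later
  phases reflects the generator's persistent rate offsets (see §3), not an
  artifact.
- The cell-cycle deconvolution assumes Gaussian 2N/4N peaks with 4N at
  exactly twice 2N and a uniform S bridge; strongly skewed peaks or
  aneuploid populations would violate it. No spectral compensation and no
  full Dean–Jett–Fox-style S-phase modelling is attempted.
- Event tables are delimited text with fixed column names; binary
  cytometry file formats are not ingested.
- The generators are calibrated for realism of the statistical tasks
  (noise level, fold changes, mixture shapes), not as a mechanistic model
  of anemone physiology.
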