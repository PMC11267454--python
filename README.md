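# polypgrowth

Quantitative analysis of feeding-dependent body-size plasticity in sea
anemones.

Sea anemone polyps such as *Nematostella vectensis* and *Aiptasia* grow
indeterminately: body size tracks food supply in both directions, with
polyps expanding more than tenfold under feeding and shrinking back over
weeks of starvation. This package provides the full quantitative toolchain
for studying that plasticity on longitudinal body-size measurements and
flow-cytometry readouts of the underlying cell populations:

- **Multi-phase growth modelling** (`polypgrowth.changepoint`) — continuous
  piecewise log-linear regression of body area over time, with exhaustive
  changepoint search, AIC selection of the number of phases (1–8), and a
  bootstrap over individuals for confidence intervals on slopes and
  changepoints. Slopes convert to doubling times (growth) or halving times
  (shrinkage) via T = ln 2 / |rate|.
- **Per-individual rate analytics** (`polypgrowth.rates`) — one OLS slope
  per polyp per phase; tests of whether growth/shrinkage rates depend on
  the size a polyp entered the phase with; a variance decomposition of
  rates over size, phase and feeding condition; log–log allometry
  (body length vs width) and a power law of body size in cell size and
  cell number, compared against the exponents predicted by isometric cell
  packing; Kaplan–Meier survivorship.
- **Cytometry quantification** (`polypgrowth.cytometry`) — a deterministic
  sequential gating cascade (bead exclusion, scatter debris, two singlet
  gates, DNA pulse-width window, 2N–4N DNA envelope) with per-gate
  provenance counts; cell-cycle fractions from the DNA histogram with a
  tail-deconvolution correction; EdU proliferation indices thresholded on a
  negative control; absolute cell counts from counting-bead spike-ins with
  dissociation-loss correction; cell-size bins calibrated on a bead
  diameter ladder.
- **Synthetic data generators** (`polypgrowth.simulate`) — seeded,
  truth-labelled cohorts (piecewise-exponential growth with per-individual
  rate spread, measurement noise, mortality hazards, and width/length
  morphometrics) and cytometry event clouds (cycle mixture, debris,
  doublets, bead spike-ins), so every estimator can be validated against
  known ground truth.
- **CLI and pipeline** (`polypgrowth.cli`, `polypgrowth.pipeline`) — a
  `polypgrowth` command with `simulate`, `fit-growth`, `rates`, `gate` and
  `run` subcommands; one master seed spawns named child streams per stage,
  so a fixed seed reproduces every output byte for byte.

## Worked example: growth phases

```python
import polypgrowth as pg

# simulate a 96-polyp cohort through two feed/starve cycles
cohort = pg.simulate_cohort(pg.nematostella_al(seed=42))

# how many growth phases does the data support?
best, aic_table = pg.select_model(cohort.trajectories, max_phases=8)
print(f"AIC selects {best.n_phases} phases, changepoints at days "
      f"{[round(c) for c in best.changepoints]}")

# bootstrap over individuals for slope CIs, converted to doubling/halving times
for s in pg.bootstrap_fit(cohort.trajectories, best, n_boot=500, seed=1):
    print(f"phase {s.phase_index + 1}: {s.kind:9s} "
          f"{'T_D' if s.kind == 'growth' else 'T_1/2'} = {s.time_days:4.1f} d "
          f"[{s.time_ci_low:.1f}, {s.time_ci_high:.1f}]")
```

Output:

```
AIC selects 4 phases, changepoints at days [9, 99, 108]
phase 1: growth    T_D =  2.4 d [2.3, 2.5]
phase 2: shrinkage T_1/2 = 27.2 d [23.5, 32.1]
phase 3: growth    T_D =  4.3 d [4.0, 4.6]
phase 4: shrinkage T_1/2 = 34.9 d [29.0, 43.2]
```

The fitted alternation — fast doubling during feeding, slow halving during
starvation, slower regrowth in the second cycle — recovers the rates the
cohort was generated with (T_D 2.4 d, T_1/2 29 d, T_D 4.5 d, T_1/2 37 d).

## Worked example: cytometry

```python
import dataclasses
import polypgrowth as pg
from polypgrowth.cytometry import analyze_sample

cfg = pg.events_day1(seed=7)                      # fed, day-1 composition
events = pg.simulate_events(cfg)
control = pg.simulate_events(dataclasses.replace(cfg, edu_fraction=0.0, seed=8))

res = analyze_sample(events, negative_control=control,
                     beads_added=cfg.beads_added_count)
g1, s, g2m = res.fractions
print(f"gated {res.n_cells_gated:,} of {res.n_events_in:,} events")
print(f"G1/G0 {g1:.1%}  S {s:.1%}  G2/M {g2m:.1%}  EdU+ {res.edu_index:.1%}")
print(f"absolute count: {res.cells_per_sample:,.0f} cells/sample")
```

Output:

```
gated 49,997 of 104,347 events
G1/G0 83.6%  S 5.2%  G2/M 11.2%  EdU+ 8.4%
absolute count: 49,997 cells/sample
```

The sample was generated with fractions (83.8%, 5.0%, 11.2%) and an 8.3%
EdU labelling rate, plus debris, doublets and two bead spike-in types that
the gating cascade removes.

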