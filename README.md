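# mekerk

Dissecting the origins of cell-to-cell variability in the MEK-ERK signalling
module from cross-sectional single-cell snapshot data.

The package implements, end to end:

* **Mechanistic model** (`mekerk.models`) — the distributive two-step
  ERK (de)phosphorylation network (9 species, 14 reactions, 20 free
  parameters: 12 cycle rates, 4 upstream-input parameters, 4 initial
  conditions), plus a processive variant for mechanism comparison.
  Deterministic dynamics via a compiled adaptive RK45 fast path with a
  stiff-capable LSODA fallback.
* **Intrinsic noise engines** (`mekerk.stochastic`) — exact Gillespie SSA
  (compiled, with the step input handled as a hard event boundary) and the
  linear noise approximation: joint mean + covariance ODEs on the
  concentration scale with explicit system size Ω.
* **Extrinsic noise** (`mekerk.population`) — independent log-normal
  parameter populations (natural-scale mean/variance hyperparameters),
  scaled Unscented Transform moment propagation in log-parameter space,
  population Monte Carlo snapshot simulation, and the law-of-total-variance
  combination of both noise layers.
* **Bayesian inference** (`mekerk.inference`) — three likelihoods
  (average-data Gaussian, intrinsic LNA Gaussian, extrinsic UT log-normal),
  an adaptive likelihood-tempered SMC sampler with systematic resampling
  and random-walk rejuvenation, log model evidence with bootstrap Monte
  Carlo error, and Bayes-factor grading (BF > 30 = "very strong").
* **Variability attribution** (`mekerk.variability`) — variance
  decomposition by parameter group (upstream / initial conditions /
  reaction rates / driving), posterior CV contributor ranking, and the λ
  input-output variability ratio scan.
* **Information metrics** (`mekerk.information`) — variance / CV / Fano
  time courses and a plug-in KDE mutual-information estimator with the
  1.06·σ·N^(−1/5) normal-reference bandwidth rule.
* **Synthetic data** (`mekerk.synthetic`) — quantitative-image-cytometry
  style snapshot generation: destructive sampling every 2 min from 0 to
  50 min, a version-stamped synthetic ground-truth fixture with three
  scenarios (extrinsic / intrinsic / driving_only).

## CLI

A single executable with subcommands:

```bash
mekerk simulate --scenario extrinsic --cells 1000 --seed 7 --out snapshot.csv
mekerk fit --likelihood extrinsic --model distributive --particles 256 \
       --seed 0 --data snapshot.csv --out-prefix fit_ext
mekerk evidence-compare fit_ext_report.json fit_int_report.json
mekerk stats --data snapshot.csv
mekerk mi --data snapshot.csv --unit nats
mekerk decompose --group upstream --engine ut
mekerk lambda-scan --sigma-k1 0.3 --sigma-k1 1.2 --sigma-k10 0.05 \
       --sigma-k10 0.12 --mode driving
mekerk run-all --seed 1 --out-dir run1     # full workflow + JSON report
```

`run-all` accepts a TOML config (see `mekerk.io.RunConfig`); CLI flags
override file values.

## Data format

Snapshot CSV: one row per cell per time point with columns
`time_min, cell_id, ppMEK, ppERK` (+ optional extras, preserved on read).
Cells are never tracked across time points; intensities are in arbitrary
units and must be nonnegative (strictly positive for the extrinsic
likelihood's log-normal support).

The reference fixture values in `mekerk.synthetic` are synthetic ground
truth chosen to reproduce the qualitative phenomenology of the biological
system; they are not measured or published values.
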