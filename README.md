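# thmrisk

Probabilistic multi-pathway cancer-risk assessment for trihalomethanes (THM)
in chlorinated tap water: Monte Carlo propagation of triangular-distributed
exposure factors through ingestion, dermal and inhalation dose equations, a
shower-stall volatilization model with a successive-shower accumulation rule
for shared bathrooms, heated-water THM formation, and duration/ventilation
sensitivity scans — fed by a synthetic water-quality generator calibrated to
published summary statistics.

## What it models

* **Sampling engine** (`thmrisk.sampling`) — seeded inverse-CDF sampling of
  triangular-distributed exposure factors (ingestion rate, shower duration,
  stall volume, flows, body weight, …), with gender-specific exposure
  duration / body weight / averaging time.
* **Water generator** (`thmrisk.water`) — four-species concentration vectors
  (TCM: three-parameter Weibull; BDCM/DBCM/TBM: normal), rejection-truncated
  to published per-species ranges. Per-species means are *derived* by backing
  published mean ingestion risks out through the ingestion dose multiplier
  (`calibrate_default_means`); an optional free-chlorine covariate and a
  Gaussian-copula correlation hook are included. A measured CSV
  (`tcm,bdcm,dbcm,tbm` in µg/L) is a drop-in replacement.
* **Shower air model** (`thmrisk.shower`) — one-compartment mass balance
  `dC/dt = a − bC` per species with two-film volatilization coefficients;
  successive back-to-back events accumulate via the averaging recursion whose
  closed form is `cair(n) = (2ⁿ−1)/2ⁿ · Ct` (the second user sees +50%, the
  third +75%, saturating below 2×). An ODE re-initialization mode and an
  inter-event ventilation-gap decay are available as labelled options.
* **Dose/risk arithmetic** (`thmrisk.risk`) — CDI for ingestion/dermal,
  heated-water concentration adjustment, body surface area, inhalation
  exposure concentration (averaging time in hours), and risk conversion via
  oral slope factors / inhalation unit risks, plus grid totals.
* **Pipeline + CLI** (`thmrisk.pipeline`, `thmrisk.cli`) — private
  (single-event) and shared (S1..S10) population runs pooled over both
  genders, distributional summaries (mean, sd, min, p10, median, p90, max;
  linear-interpolation percentiles), duration/ventilation scans with
  exponential trend fits.

## CLI

```bash
# full Monte Carlo, private stalls, summary + wide risk table + manifest
thmrisk simulate --population private --iterations 10000 --seed 1 --out runs/private

# shared stalls with 10 back-to-back events, also dump per-iteration draws
thmrisk simulate --population shared --events 10 --seed 1 --out runs/shared --draws

# sensitivity scans with per-event exponential trend fits
thmrisk scan-duration --durations 5,10,15,20,25 --events 1,3,5 --out runs/scan_t
thmrisk scan-ventilation --ventilation 0,5,10,15,20 --events 1,3,5 --out runs/scan_qg

# summarize an existing draws CSV
thmrisk report --draws runs/shared/risk_draws.csv --out runs/shared/report.csv
```

Runs accept `--config my.yaml`, a YAML file deep-merged over the shipped
defaults (`src/thmrisk/data/defaults.yaml` documents the schema), and
`--concentrations measured.csv` to replace the synthetic water generator.

## Units and conventions

* Water concentrations are µg/L; air concentrations are carried in µg/L
  inside the stall mass balance and converted ×1000 to µg/m³ only at the
  exposure-concentration boundary (`thmrisk.units`).
* Daily exposure time is `t × F / 60` h/day; the inhalation averaging time is
  the sampled AT (days) × 24.
* Ventilation scans take L/s inputs and convert ×60 into the L/min units of
  the mass balance.
* Genders are simulated separately with equal iteration counts and pooled,
  so reported means are the equal-weight gender averages.
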