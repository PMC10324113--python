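# popkit

Population pharmacokinetics for sparse steady-state oral-dosing studies:

- **`popkit.structural`** — closed-form one-compartment model with first-order
  absorption/elimination under repeated oral dosing (multidose superposition
  and steady-state forms), analytic interval AUC, half-life and Tmax.
- **`popkit.popmodel`** — hierarchical population layer: log-normal
  between-subject variability, per-group effects on log-clearance,
  additive/proportional/combined residual-error models, conditional
  log-densities, BLQ policies (exclude / LLOQ-half / censored-M3).
- **`popkit.saem`** — SAEM estimation (vectorised MH E-step with independence
  + random-walk kernels, closed-form GLS/moment M-step), Louis-identity /
  Laplace standard errors, importance-sampling marginal log-likelihood,
  error-model comparison by AIC/BIC, likelihood-ratio test.
- **`popkit.individual`** — empirical-Bayes conditional modes (batched Newton),
  optional MCMC refinement and conditional means, derived individual
  AUC(0-tau) and half-life, eta-shrinkage diagnostics.
- **`popkit.inference`** — group AUC summaries, percent change, two-sample
  variance-ratio F test, Brown-Forsythe, one-way ANOVA, eta-covariate
  association, Pearson/Spearman correlation (exact permutation p for n <= 9),
  2^-ddCt fold change.
- **`popkit.simulate`** — synthetic study generator with retained ground truth
  (99 subjects, 4 treatment arms, 3 mg/kg daily oral dosing for 5 days,
  sparse 3-4 samples/subject from a 6-point menu, LLOQ censoring at
  0.5 ng/mL), plus correlated expression covariates.
- **`popkit.io` / `popkit.cli`** — canonical long-format CSV, YAML configs,
  versioned JSON reports, and a `popkit` command-line pipeline.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (in-print arithmetic
checks plus simulation-based parameter-recovery and error-model-selection
suites); the remaining files are per-module unit and property tests.

## CLI

All randomness flows from `--seed`; outputs land under `--out-dir`.

```sh
popkit simulate --seed 1 --out-dir run           # data.csv + truth.csv + simulation.json
popkit fit run/data.csv --seed 1 --out-dir run   # fit.json + trajectories.csv
popkit ebe run/data.csv run/fit.json --out-dir run
popkit derive run/individual_estimates.csv --out-dir run
popkit variance-test run/individual_estimates.csv --groups TAC,TAC+ATB --out-dir run
popkit covariate-test run/individual_estimates.csv --out-dir run
popkit correlate run/individual_estimates.csv expr.csv --method pearson --out-dir run
popkit compare-errors run/data.csv --seed 1 --out-dir run
popkit report --out-dir run                      # report.json + report.md
```

## Conventions

- Units: ng, L, h internally; concentrations exposed in ng/mL, AUC in
  ng·h/mL.
- Random-effect order is (log-CL, log-V, log-Ka) everywhere.
- Time is hours since the last dose; the dose event is at t=0 of the
  interval.
- Assumed (non-published) constants in reports carry an `assumption` flag.
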