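# drugcourts

Bayesian modeling of county-level illicit-opioid overdose mortality and
the effect of drug courts, with spatially structured growth rates,
exposure-by-covariate effect heterogeneity, and posterior-predictive
counterfactual scenarios.

The model is a Poisson autoregressive count panel: each county's baseline
year has its own log death rate, and every subsequent year's rate is the
previous year's rate times exponentiated transition terms — a global
drift, covariate effects, a drug-court effect (optionally interacted with
every covariate), and an intrinsic conditional autoregressive (ICAR)
spatial effect that gives each county its own average growth rate.
Exponentiated coefficients are therefore year-over-year death-rate
ratios.

## Package layout

| module | contents |
| --- | --- |
| `drugcourts.panel` | county-year panel and adjacency graph loading/validation |
| `drugcourts.covariates` | targeting index + tertiles, PCA poverty/healthcare indices, design matrices |
| `drugcourts.model` | log-densities: Poisson likelihood, ICAR kernel, priors, posterior |
| `drugcourts.inference` | HMC-within-Gibbs sampler, diagnostics, rate-ratio summaries |
| `drugcourts.counterfactual` | scenario rewrites, posterior-predictive counts, county/state aggregation |
| `drugcourts.synthetic` | lattice graphs, ICAR draws, covariate/panel simulation, parameter recovery |

Inference is pure numpy/scipy: the autoregressive recursion is linear in
the parameters once unrolled, so the sampler uses exact gradients, a
dense Hessian mass matrix computed at the posterior mode, a conjugate
Gibbs update for the ICAR precision, and an interweaved scale move that
keeps the precision mixing. Fits are deterministic given a seed.

## Command line

```sh
# simulate a synthetic county system from known parameters
drugcourts simulate --config truth.json --seed 1 --out panel.csv --adjacency-out edges.csv

# validate panel/adjacency invariants
drugcourts validate --panel panel.csv --adjacency edges.csv

# fit model 1 (main effects) or model 2 (drug-court interactions)
drugcourts fit --panel panel.csv --adjacency edges.csv --model 2 --seed 1 \
    --out draws.csv --summary-out summary.csv --transforms-out transforms.json

# counterfactual scenarios from saved draws
drugcourts counterfactual --draws draws.csv --panel panel.csv --adjacency edges.csv \
    --scenario no_courts --transforms transforms.json \
    --county-out county.csv --statewide-out statewide.csv
```

Built-in scenarios: `no_courts`, `universal_courts`,
`universal_no_high_targeting`; custom scenarios via `--scenario-file`.

## Data formats

Panel CSV: one row per (county, year) over a complete rectangular window
(default 2017–2023), with columns `county_id`, `year`, `deaths`,
`population`, `drug_court`, `possession_arrests`, `persons_arrests`,
`property_arrests`, `crime_rate`, `hidta`, `democrat_da`, `urban`, `mua`,
`uninsured_pct`, `poverty_pct`, `unemployed_pct`, `disabled_pct`,
`food_stamps_pct`, `public_assistance_pct`, `no_hs_diploma_pct`,
`otp_count`. Covariates are required from the second year onward; the
first (baseline) year only needs deaths and population.

Adjacency: two-column CSV edge list (`county_a`, `county_b`) or a JSON
object mapping each county to its neighbor list.

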