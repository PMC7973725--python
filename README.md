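# hurdlemap

Two-part (hurdle) Bayesian spatial modelling of rare-disease prevalence and
incidence from non-random referral-unit cohorts, together with a synthetic
census-tract data generator that reproduces the statistical structure such an
analysis assumes: endogenous selection, Matérn-correlated spatial risk and
zero-inflated tract counts.

## What it does

Disease registries built from referral units are not random samples: the
probability that a case is observed varies with geography and with
unobserved factors that also drive risk (endogenous selection), so crude
rates and age/sex standardisation are both biased.  `hurdlemap` implements a
joint two-part model:

* **Part 1** — a binomial GLMM for the probability of an at-risk person
  being an observed case (logit link, tract covariates, iid heterogeneity,
  shared Matérn spatial field, optional selection covariates such as
  distance to the referral centre).
* **Part 2** — a zero-inflated Poisson GLMM for observed tract counts (log
  link, same covariates, its own heterogeneity, the shared spatial field,
  an RW1 yearly effect for incidence, `log(pop_over16)` offset).  The
  part-1 probabilities enter part 2 as weightings: by default their log,
  anchored to an assumed mean coverage, is an offset so the ZIP mean models
  observed counts as thinned true counts (`log_prob_offset`); inverse-
  probability weighting of the part-2 likelihood is available behind the
  `likelihood_weight` flag.

Both parts are estimated jointly under penalised-complexity (PC) priors by a
self-contained nested Laplace approximation (inner Newton over fixed effects
and latent fields, outer optimisation of the hyperparameters, Gaussian-
mixture posterior draws).  Region rates come from the posterior of expected
*true* (un-thinned) counts over population; the two regions are pooled by
intersecting their 95% credibility intervals.

Because the absolute level of an endogenous selection process is not
identifiable from observed counts alone, the mean observation probability
(referral-unit coverage) is an explicit free parameter
(`TwoPartModelSpec.coverage_mean`).

## Package layout

| module | contents |
| --- | --- |
| `hurdlemap.synthetic` | seeded landscape / disease / selection generator, CSV + GeoJSON I/O |
| `hurdlemap.deprivation` | sequential-PCA deprivation index, quintile coding |
| `hurdlemap.model` | Matérn covariance, RW1 and PC-prior log-densities, ZIP log-pmf, both linear predictors, joint log-likelihood |
| `hurdlemap.inference` | Laplace fitting engine, posterior container, observation weights, posterior summaries |
| `hurdlemap.rates` | region/tract rate estimation, interval pooling, descriptive computations, crude comparator |
| `hurdlemap.pipeline` / `hurdlemap.cli` | run configuration, simulation study driver, published-table pooling, `hurdlemap` CLI |

## CLI

```bash
hurdlemap simulate --out-dir runs/sim --n-tracts 100 --seed 1
hurdlemap deprivation runs/indicators.csv --out runs/deprivation.csv
hurdlemap fit runs/sim/tracts_observed.csv --out-dir runs/fit --coverage 0.6
hurdlemap pool runs/estimates.csv --out runs/pooled.csv
hurdlemap study --out-dir runs/study --replicates 20 --seed 1
hurdlemap reproduce-tables table6.csv --out pooled.csv
```

`simulate` writes true and observed tract tables (CSV), patient records
(CSV) and square tract tiles (GeoJSON).  `study` runs the full
simulate-fit-estimate loop and reports coverage of the truth by the
corrected intervals versus the crude comparator.

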