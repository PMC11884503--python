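# brcapool

Bayesian hierarchical pooling of somatic *BRCA1/2* pathogenic-variant
prevalence across metastatic prostate-cancer cohorts.

## The problem

Tumors with pathogenic *BRCA1* or *BRCA2* variants respond to PARP
inhibitors, so universal somatic testing of metastatic prostate-cancer
patients is increasingly common — but how often is a test positive?
Published cohorts disagree (raw rates from 0/42 to 8/49), and small cohorts
give very unstable estimates. In particular, a cohort with **zero** positives
out of 42 patients says almost nothing on its own: the naive estimate 0% is
implausible given every other cohort.

`brcapool` treats the per-cohort prevalences as exchangeable draws from a
population distribution and pools them:

```
theta_i ~ Beta(mu*kappa, (1-mu)*kappa)      # population of cohort prevalences
P_i     ~ Binomial(N_i, theta_i)            # observed positives
mu      ~ Beta(1, 1)                        # population mean prevalence
kappa   ~ Gamma(1, 0.1)                     # concentration (shape-rate; mean 10)
```

The mean/concentration Beta parametrization makes the hyperparameters
directly interpretable: `mu` is the worldwide mean prevalence, `kappa`
controls how tightly cohorts cluster around it (larger `kappa` = cohorts more
alike; `Var[theta] = mu(1-mu)/(kappa+1)`). The hierarchical ("adjusted")
estimate of each `theta_i` borrows strength from all cohorts, shrinking small
cohorts toward `mu`. The comparator "unadjusted" estimate is the independent
conjugate posterior `rho_i ~ Beta(1+P_i, 1+N_i-P_i)` per cohort.

Inference runs two ways, which cross-validate each other:

- **MCMC** (`run_mcmc`): collapsed Metropolis-within-Gibbs — adaptive 2-D
  random walk on `(logit mu, log kappa)` against the analytic beta-binomial
  marginal likelihood, plus exact conjugate draws of each `theta_i`; split
  R-hat and effective-sample-size diagnostics included.
- **Quadrature oracle** (`grid_posterior`): deterministic 2-D grid quadrature
  of the marginalized hyperparameter posterior; each `theta_i` posterior is
  then an exact mixture of Beta distributions, with no Monte Carlo error.

A synthetic-data module generates cohort tables from the same generative
model and runs parameter-recovery, interval-coverage, and partial-pooling
efficiency experiments.

## Worked example

The seven published cohorts ship with the package:

```sh
brcapool fit --paper-data --seed 1 --outdir fit_out
```

prints the per-cohort report (percent, medians with equal-tailed 95%
credible intervals):

```
               label  adjusted_median_pct adjusted_cdi_pct adjusted_r_hat  unadjusted_median_pct unadjusted_cdi_pct  shrinkage_pct
       Robinson 2015                 12.3         8.0-17.9          1.000                   13.0           8.3-19.0            0.7
          Mateo 2015                 14.6         7.6-24.8          1.000                   17.2           8.6-29.1            2.6
           Mota 2020                  9.5         4.3-17.3          1.000                   10.2           4.4-19.0            0.7
    Tukachinsky 2021                  8.5         6.8-10.5          1.000                    8.5           6.8-10.6            0.0
Martinez Chanza 2021                  9.9         5.9-15.3          1.000                   10.3           6.0-16.0            0.4
         Uemura 2022                 12.9         8.3-18.7          1.000                   13.6           8.7-19.8            0.7
        Barroso 2024                  3.1         0.1-10.1          1.000                    1.6            0.1-8.2            1.5
```

Reading the last row: the zero-positive cohort's prevalence is estimated at
**3.1%** (95% CdI roughly 0.1–10.1%), not 0% — the other cohorts pull it up —
while the largest cohort (N=837) is essentially unmoved by pooling
(shrinkage 0.0 pp). The hyperparameter summaries (written to
`hyperparameters.csv`) put the population mean prevalence at about 11.6%
and the concentration at about 19. All split R-hat values round to 1.000,
indicating well-mixed chains. The same analysis without any sampling:

```sh
brcapool oracle --paper-data --outdir oracle_out
```

Other subcommands: `simulate` (draw a synthetic cohort table), `recover`
(coverage/bias/RMSE experiment over many simulated tables), `report`
(re-render the table from an exported draws CSV).

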