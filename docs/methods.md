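# Methods

## Model

Data are per-cohort counts: `N_i` patients with somatic *BRCA1/2* test
results and `P_i` positives, for `K` cohorts. The hierarchical model is

    theta_i | mu, kappa ~ Beta(mu*kappa, (1-mu)*kappa)     i = 1..K
    P_i | theta_i       ~ Binomial(N_i, theta_i)
    mu                  ~ Beta(1, 1)
    kappa               ~ Gamma(shape=1, rate=0.1)

`mu` in (0,1) is the population mean prevalence and `kappa > 0` the
concentration of cohort prevalences around it; the implied prevalence
variance is `mu(1-mu)/(kappa+1)`, so large `kappa` approaches complete
pooling and small `kappa` leaves cohorts nearly independent. The
"unadjusted" comparator model drops the hierarchy: independent
`rho_i ~ Beta(1,1)` with the same binomial likelihood, giving conjugate
posteriors `Beta(1+P_i, 1+N_i-P_i)` in closed form.

The model assumes cohorts are exchangeable given (mu, kappa) — i.e. that
between-cohort differences (geography, founder effects, assay mix) are
adequately described by a single Beta population distribution — and that
within a cohort every tested patient is an independent Bernoulli trial with
a common prevalence. Covariates, within-cohort heterogeneity and
non-exchangeable structure are out of scope.

### Priors

The mean prevalence carries a flat Beta(1,1) prior. For the concentration we
use Gamma(shape=1, rate=0.1) — an Exponential with mean 10. This choice is
deliberate: the prior must be proper yet heavy enough in the upper tail that
the data can place `kappa` in the tens when cohorts genuinely cluster. A
superficially similar Gamma(0.1, 1) prior (mean 0.1, density exploding at 0
with an `e^-kappa` tail) effectively forbids `kappa > ~10`: on these data it
drags the posterior to `kappa ≈ 2` and `mu ≈ 21%`, i.e. the prior, not the
data, decides the answer. Sensitivity: with Gamma(1, 0.1) vs the flatter
Gamma(0.1, 0.01), the seven-cohort `mu` median moves by under 1 pp while the
`kappa` median (which only 7 cohorts inform) moves substantially — the
concentration is the quantity to treat cautiously, as its wide credible
interval already signals. Both hyperprior constants are overridable through
`PriorSpec` / the CLI flags.

All densities are evaluated in log space via log-gamma/log-beta functions
(N=837 overflows naive factorials), with binomial combinatorial constants
included so that marginal likelihoods are proper probabilities. `theta`,
`mu` are handled strictly on the open interval; boundary values are
rejected, not clamped.

## MCMC

The joint posterior factorizes exactly:

    p(mu, kappa, theta | data) = p(mu, kappa | data) * prod_i p(theta_i | mu, kappa, data)

where `p(mu, kappa | data)` uses the analytic beta-binomial marginal
`log C(N,P) + log B(P+a, N-P+b) - log B(a,b)` (a = mu*kappa,
b = (1-mu)*kappa) and each conditional is conjugate,
`theta_i | mu, kappa, data ~ Beta(P_i + a, N_i - P_i + b)`.

The sampler is therefore a collapsed Metropolis-within-Gibbs:

1. an adaptive Gaussian random-walk Metropolis chain on the two
   unconstrained coordinates `(logit mu, log kappa)`, targeting the
   marginalized posterior with the transform Jacobian included;
2. exact conjugate Beta draws of all `theta_i` at each recorded state.

Warmup adapts the proposal: Robbins–Monro tuning of the global log step size
toward a 0.30 acceptance rate (decay `t^-0.6`) and a running empirical
covariance (engaged after 100 iterations, refreshed every 50). Adaptation is
frozen at the end of warmup, so the recorded segment is a time-homogeneous
Markov chain. Chains initialize from independent hyperprior draws (kappa
clamped to [1e-3, 1e3] to avoid numerically flat starting regions), giving
overdispersed starts that make split R-hat meaningful.

Defaults: 4 chains, 2000 warmup iterations, 5000 recorded draws per chain
with thinning 10 (i.e. 50 000 post-warmup Metropolis steps per chain; ~5 s
for the seven-cohort table). Thinning is cheap here because each step costs
two vectorized log-beta evaluations, and it leaves recorded hyperparameter
draws close to independent — which is why effective sample sizes approach
the raw draw count and split R-hat values round to 1.000 at three decimals.
Per-chain generators are spawned deterministically from the base seed
(`SeedSequence(base_seed).spawn`): identical inputs give bit-identical
output. Chains run sequentially.

The unadjusted model has an MCMC path too (coordinate-wise random-walk
Metropolis on `logit rho_i`, target acceptance 0.44), used only to
cross-validate the closed-form conjugate posteriors. A fixed-(mu, kappa)
harness mode isolates the theta update; because the theta update is an exact
conjugate draw by construction, its Kolmogorov–Smirnov check guards the
update's algebra rather than exercising an approximation.

### Diagnostics

`split_rhat` is the classic split formulation: each chain halved, R-hat =
sqrt((((n-1)/n)W + B/n)/W) over the 2m half-chains (not rank-normalized;
values are reported to three decimals). Zero within-chain variance returns
NaN with a warning. `effective_sample_size` combines per-chain FFT
autocovariances with the between-chain variance and truncates the lag sum by
Geyer's initial monotone positive sequence; super-efficient (negatively
autocorrelated) chains can report ESS above the raw count, which summary
reports cap at the total. Both statistics are cross-checked against an
independent implementation in the test suite. `run_mcmc` warns (does not
fail) above R-hat 1.01; the CLI `fit` exits nonzero above 1.05 with outputs
still written.

## Quadrature oracle

The same marginalization makes the hyperparameter posterior two-dimensional,
so a deterministic quadrature gives reference answers with no Monte Carlo
error. Nodes are uniform on `(logit mu, log kappa)` — the log scale is what
resolves the prior's lower kappa tail — with trapezoid cell weights and the
grid-parametrization Jacobian; defaults span logit(mu) in [-9, 4] and
log(kappa) in [-12, 9] with 400 nodes per axis. Normalized node weights sum
to 1 (checked to 1e-10). If the outermost grid ring carries more than 1e-6
of the mass, a warning flags posterior leakage off-grid — a simple, auditable
failure mode preferred over adaptive domains.

Hyperparameter quantiles interpolate the discrete marginal CDF (each node's
mass centered on it). Each `theta_i` posterior is the weight-mixture of
conjugate Beta distributions over nodes; quantiles come from bracketed root
finding (Brent) on the monotone mixture CDF to 1e-10, with components below
1e-14 of the heaviest weight pruned. When the mixture holds mass beyond the
bracket `[1e-12, 1-1e-12]` — possible for zero-count cohorts under very
small kappa, where Beta shape parameters fall far below 1 — the quantile is
clamped to the bracket edge. Halving the default grid spacing moves reported
quantiles by well under 0.05 percentage points on the seven-cohort table.

## Reporting

Every estimate is the posterior median with the equal-tailed 95% credible
interval (2.5%/97.5% quantiles). Draw quantiles use linear interpolation
between order statistics ("type 7"), matching the default of mainstream
numerical stacks so digits are reproducible. Percentages render to one
decimal (round half to even), R-hat to three decimals; report CSVs carry
unrounded parallel columns because rounding is a presentation concern.
Shrinkage is the absolute difference between the adjusted and unadjusted
medians. Note the direction of pooling is anchored at the raw rate `P_i/N_i`,
not at the unadjusted median: the unadjusted Beta(1,1) prior itself nudges
medians toward 0.5, so an adjusted median can legitimately sit below both
the unadjusted median and the population mean (the 6/64 cohort does).

On the bundled table the closed-form unadjusted median for the zero-positive
cohort is 1.6% (lower 95% bound 0.06%); a sampled variant of the same
quantity can print 1.7%/0.2% — the package reports the exact closed form.

## Synthetic data and validation

`simulate_cohorts` runs the generative model forward with a seeded,
splittable PRNG (per-replicate substreams from `SeedSequence((seed,
replicate))`), so replicates are independent and individually reproducible.
`recovery_experiment` refits each simulated table — by the quadrature oracle
by default, keeping Monte Carlo noise out of coverage estimates — and
reports bias, 95%-interval coverage, and RMSE of adjusted vs unadjusted
prevalence estimators against the simulated truth.

Two coverage regimes matter and the package exposes both:

- **Fixed truth** (default): frequentist coverage at one chosen (mu, kappa).
  For the population mean this typically *exceeds* 95% (e.g. ~99% at
  mu=0.1, kappa=20 with the seven published cohort sizes) because the mu
  posterior is wide when only seven cohorts inform it — honest intervals,
  conservatively calibrated at that point.
- **Truth from prior** (`truth_from_prior=True`): each replicate's
  (mu, kappa) is drawn from the fitting hyperprior, the regime in which 95%
  Bayesian intervals cover at exactly the nominal rate (simulation-based
  calibration). The acceptance suite checks this at 200 replicates against
  the exact binomial band.

The partial-pooling payoff is checked as an estimator-efficiency experiment:
over 200 fixed-truth replicates, the adjusted median's RMSE for the smallest
cohort (N=42) must not exceed the unadjusted median's (observed: ~0.039 vs
~0.047, with the advantage shrinking as N grows — the largest cohort's two
estimators are nearly identical).

What the synthetic generator does *not* emulate: non-Beta between-cohort
heterogeneity, within-cohort covariate structure, assay sensitivity
differences, or selection effects in who gets tested. Passing recovery tests
therefore show the inference machinery is correct under the model's own
assumptions, not that the model is right for any particular real dataset.

## Problem sizes used in the test and acceptance runs

MCMC fits use the default 4x5000 (thin 10) for the bundled table and
4x1500 (thin 5) for the ten synthetic agreement tables; oracle fits use the
400x400 default grid for the bundled table, 200x200 for the agreement
tables, and 160x160 inside the 200-replicate recovery experiments, where
the grid-resolution error is orders of magnitude below the tolerances being
checked. MCMC-vs-oracle agreement is asserted within 3 Monte Carlo standard
errors of each empirical quantile.

## Known limitations

- `kappa` is weakly identified from seven cohorts; its posterior (and any
  statement about between-population heterogeneity) is prior-sensitive.
- The random-walk stage is not gradient-based; for much larger K (hundreds
  of cohorts) the 2-D marginal stays 2-D, so the design scales, but the
  conjugate-draw stage assumes the Beta-binomial structure — covariates on
  mu would break the collapse.
- The oracle's fixed grid must contain the posterior; pathological tables
  (all zeros with huge N) can push mass to the grid edge, which is flagged
  but not auto-repaired.
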