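"""MCMC for the hierarchical model and its diagnostics.

Sampler design
--------------
The posterior factorizes as p(mu, kappa | data) * prod_i p(theta_i | mu,
kappa, data), where the first factor uses the analytic beta-binomial marginal
and the second is conjugate Beta.  The sampler therefore runs an adaptive
random-walk Metropolis chain on the two unconstrained hyperparameters
(logit mu, log kappa) targeting the marginalized posterior, and completes each
recorded state with exact draws theta_i ~ Beta(P_i + mu*kappa,
N_i - P_i + (1-mu)*kappa).  This is a valid Metropolis-within-Gibbs scheme
whose theta components mix perfectly; thinning the hyper chain (default 10)
leaves recorded hyper draws close to independent, which is what makes the
split-R-hat diagnostics of a default run round to 1.000.

Proposal scale and covariance adapt during warmup only (Robbins-Monro on the
log step size toward a 0.3 acceptance rate, running empirical covariance);
adaptation is frozen afterwards so the recorded portion is a time-homogeneous
Markov chain.  Chains run sequentially with per-chain generators spawned
deterministically from the base seed: identical inputs give bit-identical
output.

An ``independent`` model variant samples the no-pooling prevalences rho_i
(independent Beta(1,1)-binomial per cohort) by coordinate-wise random-walk
Metropolis on the logit scale; it exists to cross-validate the closed-form
conjugate posteriors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .cohort_io import CohortTable
from .model import PriorSpec

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "run_mcmc",
    "split_rhat",
    "effective_sample_size",
]

_TARGET_ACCEPT_2D = 0.30   # joint 2-D proposal
_TARGET_ACCEPT_1D = 0.44   # coordinate-wise proposals
_INIT_RETRIES = 100


@dataclass(frozen=True)
class SamplerConfig:
    """Run lengths and seeding for :func:`run_mcmc`.

    ``n_draws`` counts recorded post-warmup draws per chain; with ``thin`` > 1
    the underlying hyper chain advances ``thin`` Metropolis steps per recorded
    draw.  ``n_chains`` must be at least 2 so split-R-hat is defined.
    """

    n_chains: int = 4
    n_warmup: int = 2000
    n_draws: int = 5000
    thin: int = 10
    base_seed: int = 0
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (required for split R-hat)")
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")
        if self.n_warmup < 0 or self.thin < 1:
            raise ValueError("n_warmup must be >= 0 and thin >= 1")


@dataclass(frozen=True)
class PosteriorDraws:
    """Per-chain posterior draws on the constrained scale.

    ``draws`` maps parameter name ("mu", "kappa", "theta[<label>]" — or
    "rho[<label>]" for the independent model) to an array of shape
    (n_chains, n_draws).
    """

    param_names: tuple[str, ...]
    draws: dict[str, np.ndarray]
    config: SamplerConfig
    accept_rate: np.ndarray  # per chain, post-warmup
    model: str = "hierarchical"
    table_labels: tuple[str, ...] = field(default_factory=tuple)

    def array(self, name: str) -> np.ndarray:
        if name not in self.draws:
            raise KeyError(f"unknown parameter {name!r}; have {list(self.draws)}")
        return self.draws[name]

    def flat(self, name: str) -> np.ndarray:
        return self.array(name).ravel()

    @property
    def n_total(self) -> int:
        return self.config.n_chains * self.config.n_draws

    def rhat(self, name: str) -> float:
        return split_rhat(self.array(name))

    def ess(self, name: str, cap_at_total: bool = True) -> float:
        return effective_sample_size(self.array(name), cap_at_total=cap_at_total)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        frames = []
        n_chains, n_draws = self.config.n_chains, self.config.n_draws
        chain_idx = np.repeat(np.arange(n_chains), n_draws)
        iter_idx = np.tile(np.arange(n_draws), n_chains)
        for name in self.param_names:
            frames.append(
                pd.DataFrame(
                    {
                        "chain": chain_idx,
                        "iteration": iter_idx,
                        "parameter": name,
                        "value": self.draws[name].ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def draws_from_dataframe(df: pd.DataFrame, model: str = "hierarchical") -> PosteriorDraws:
    """Rebuild a :class:`PosteriorDraws` from its long-format CSV export."""
    required = {"chain", "iteration", "parameter", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"draws frame must have columns {sorted(required)}")
    names = tuple(df["parameter"].unique())
    chains = np.sort(df["chain"].unique())
    arrays = {}
    for name in names:
        sub = df[df["parameter"] == name]
        arrays[name] = np.stack(
            [
                sub[sub["chain"] == c].sort_values("iteration")["value"].to_numpy()
                for c in chains
            ]
        )
    n_chains, n_draws = arrays[names[0]].shape
    cfg = SamplerConfig(
        n_chains=max(n_chains, 2), n_warmup=0, n_draws=max(n_draws, 100), thin=1
    )
    labels = tuple(
        n[n.index("[") + 1 : -1] for n in names if "[" in n
    )
    return PosteriorDraws(
        param_names=names,
        draws=arrays,
        config=cfg,
        accept_rate=np.full(n_chains, np.nan),
        model=model,
        table_labels=labels,
    )


# --------------------------------------------------------------------------
# target densities on the unconstrained scale


def _hyper_log_target(z: np.ndarray, n: np.ndarray, p: np.ndarray, prior: PriorSpec) -> float:
    """Marginalized log posterior of (logit mu, log kappa), Jacobian included."""
    z_mu, z_ka = z
    if abs(z_mu) > 700 or abs(z_ka) > 700:
        return -np.inf
    mu = special.expit(z_mu)
    kappa = np.exp(z_ka)
    if not (0.0 < mu < 1.0) or not np.isfinite(kappa) or kappa <= 0:
        return -np.inf
    a = mu * kappa
    b = (1.0 - mu) * kappa
    ll = np.sum(special.betaln(p + a, n - p + b) - special.betaln(a, b))
    lp = (
        (prior.mu_alpha - 1.0) * np.log(mu)
        + (prior.mu_beta - 1.0) * np.log1p(-mu)
        + (prior.kappa_shape - 1.0) * np.log(kappa)
        - prior.kappa_rate * kappa
    )
    jac = (z_mu - 2.0 * np.logaddexp(0.0, z_mu)) + z_ka
    out = ll + lp + jac
    return float(out) if np.isfinite(out) else -np.inf


def _init_hyper(rng: np.random.Generator, prior: PriorSpec) -> np.ndarray:
    mu0 = float(np.clip(rng.beta(prior.mu_alpha, prior.mu_beta), 1e-6, 1 - 1e-6))
    kappa0 = float(np.clip(rng.gamma(prior.kappa_shape, 1.0 / prior.kappa_rate), 1e-3, 1e3))
    return np.array([special.logit(mu0), np.log(kappa0)])


def _run_hyper_chain(
    rng: np.random.Generator,
    n: np.ndarray,
    p: np.ndarray,
    prior: PriorSpec,
    config: SamplerConfig,
    fixed_hyper: tuple[float, float] | None,
):
    """One chain: returns (mu, kappa, thetas) arrays and the acceptance rate."""
    k_cohorts = len(n)
    mu_out = np.empty(config.n_draws)
    ka_out = np.empty(config.n_draws)
    th_out = np.empty((config.n_draws, k_cohorts))

    if fixed_hyper is not None:
        mu_c, ka_c = float(fixed_hyper[0]), float(fixed_hyper[1])
        mu_out[:] = mu_c
        ka_out[:] = ka_c
        a = p + mu_c * ka_c
        b = (n - p) + (1.0 - mu_c) * ka_c
        th_out[:] = rng.beta(a, b, size=(config.n_draws, k_cohorts))
        return mu_out, ka_out, th_out, np.nan

    z = _init_hyper(rng, prior)
    lt = _hyper_log_target(z, n, p, prior)
    tries = 0
    while not np.isfinite(lt):
        tries += 1
        if tries > _INIT_RETRIES:
            raise RuntimeError("could not find a finite-density initial point for MCMC")
        z = _init_hyper(rng, prior)
        lt = _hyper_log_target(z, n, p, prior)

    log_s = np.log(0.5)
    cov = np.eye(2)
    chol = np.linalg.cholesky(cov)
    mean_acc = np.zeros(2)
    cov_acc = np.zeros((2, 2))
    n_acc = 0

    def step(z, lt, chol, s):
        prop = z + s * (chol @ rng.standard_normal(2))
        lt_prop = _hyper_log_target(prop, n, p, prior)
        if np.log(rng.uniform()) < lt_prop - lt:
            return prop, lt_prop, True
        return z, lt, False

    # warmup with adaptation
    for t in range(config.n_warmup):
        z, lt, accepted = step(z, lt, chol, np.exp(log_s))
        if config.adapt:
            log_s += (t + 1.0) ** (-0.6) * ((1.0 if accepted else 0.0) - _TARGET_ACCEPT_2D)
            n_acc += 1
            delta = z - mean_acc
            mean_acc += delta / n_acc
            cov_acc += np.outer(delta, z - mean_acc)
            if n_acc > 100 and t % 50 == 0:
                emp = cov_acc / (n_acc - 1) + 1e-8 * np.eye(2)
                chol = np.linalg.cholesky(emp)

    # frozen sampling phase
    s = np.exp(log_s)
    accepted_ct = 0
    total_steps = config.n_draws * config.thin
    for i in range(total_steps):
        z, lt, accepted = step(z, lt, chol, s)
        accepted_ct += accepted
        if (i + 1) % config.thin == 0:
            j = (i + 1) // config.thin - 1
            mu = float(special.expit(z[0]))
            kappa = float(np.exp(z[1]))
            mu_out[j] = mu
            ka_out[j] = kappa
            a = p + mu * kappa
            b = (n - p) + (1.0 - mu) * kappa
            th_out[j] = rng.beta(a, b)
    return mu_out, ka_out, th_out, accepted_ct / total_steps


def _run_independent_chain(
    rng: np.random.Generator,
    n: np.ndarray,
    p: np.ndarray,
    prior: PriorSpec,
    config: SamplerConfig,
):
    """Coordinate-wise RWM on logit(rho_i) for the no-pooling model."""
    k = len(n)
    a0, b0 = prior.mu_alpha, prior.mu_beta

    def log_target(z):
        rho = special.expit(z)
        lp = (p + a0 - 1.0) * np.log(rho) + (n - p + b0 - 1.0) * np.log1p(-rho)
        return lp + z - 2.0 * np.logaddexp(0.0, z)

    z = special.logit(np.clip(rng.beta(a0, b0, size=k), 1e-6, 1 - 1e-6))
    lt = log_target(z)
    log_s = np.full(k, np.log(1.0))
    for t in range(config.n_warmup):
        prop = z + np.exp(log_s) * rng.standard_normal(k)
        lt_prop = log_target(prop)
        acc = np.log(rng.uniform(size=k)) < lt_prop - lt
        z = np.where(acc, prop, z)
        lt = np.where(acc, lt_prop, lt)
        if config.adapt:
            log_s += (t + 1.0) ** (-0.6) * (acc.astype(float) - _TARGET_ACCEPT_1D)
    s = np.exp(log_s)
    out = np.empty((config.n_draws, k))
    accepted_ct = 0
    total_steps = config.n_draws * config.thin
    for i in range(total_steps):
        prop = z + s * rng.standard_normal(k)
        lt_prop = log_target(prop)
        acc = np.log(rng.uniform(size=k)) < lt_prop - lt
        z = np.where(acc, prop, z)
        lt = np.where(acc, lt_prop, lt)
        accepted_ct += acc.mean()
        if (i + 1) % config.thin == 0:
            out[(i + 1) // config.thin - 1] = special.expit(z)
    return out, accepted_ct / total_steps


def run_mcmc(
    table: CohortTable,
    prior: PriorSpec = PriorSpec(),
    config: SamplerConfig = SamplerConfig(),
    model: str = "hierarchical",
    fixed_hyper: tuple[float, float] | None = None,
) -> PosteriorDraws:
    """Draw posterior samples for the hierarchical (or independent) model.

    Parameters
    ----------
    model
        "hierarchical" samples (mu, kappa, theta_1..theta_K); "independent"
        samples the no-pooling rho_i under a Beta(mu_alpha, mu_beta) prior.
    fixed_hyper
        Optional (mu, kappa) pair; when given, the hyperparameters are held
        fixed and only the conjugate theta draws are produced.  Test harness
        mode for validating the theta update in isolation.

    Identical inputs (including ``config.base_seed``) produce bit-identical
    draws.  A RuntimeWarning (not an error) is emitted if any split R-hat
    exceeds 1.01.
    """
    if model not in ("hierarchical", "independent"):
        raise ValueError(f"unknown model {model!r}")
    n = np.asarray(table.n_tested, dtype=float)
    p = np.asarray(table.n_positive, dtype=float)
    seeds = np.random.SeedSequence(config.base_seed).spawn(config.n_chains)

    if model == "independent":
        rho = np.empty((config.n_chains, config.n_draws, len(table)))
        acc = np.empty(config.n_chains)
        for c in range(config.n_chains):
            rng = np.random.default_rng(seeds[c])
            rho[c], acc[c] = _run_independent_chain(rng, n, p, prior, config)
        names = tuple(f"rho[{lab}]" for lab in table.labels)
        draws = {name: rho[:, :, i] for i, name in enumerate(names)}
    else:
        mu = np.empty((config.n_chains, config.n_draws))
        ka = np.empty((config.n_chains, config.n_draws))
        th = np.empty((config.n_chains, config.n_draws, len(table)))
        acc = np.empty(config.n_chains)
        for c in range(config.n_chains):
            rng = np.random.default_rng(seeds[c])
            mu[c], ka[c], th[c], acc[c] = _run_hyper_chain(
                rng, n, p, prior, config, fixed_hyper
            )
        names = ("mu", "kappa") + tuple(f"theta[{lab}]" for lab in table.labels)
        draws = {"mu": mu, "kappa": ka}
        for i, lab in enumerate(table.labels):
            draws[f"theta[{lab}]"] = th[:, :, i]

    result = PosteriorDraws(
        param_names=names,
        draws=draws,
        config=config,
        accept_rate=acc,
        model=model,
        table_labels=tuple(table.labels),
    )
    if fixed_hyper is None:
        worst = max(
            (split_rhat(arr) for arr in draws.values()),
            key=lambda r: -1.0 if np.isnan(r) else r,
        )
        if np.isfinite(worst) and worst > 1.01:
            warnings.warn(
                f"largest split R-hat is {worst:.4f} > 1.01; chains may not have converged",
                RuntimeWarning,
                stacklevel=2,
            )
    return result


# --------------------------------------------------------------------------
# convergence diagnostics


def _as_chains(draws) -> np.ndarray:
    arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected (n_chains, n_draws) array, got shape {arr.shape}")
    return arr


def split_rhat(draws) -> float:
    """Split R-hat: potential scale reduction over half-chains.

    Each of the m chains is split in half; with W the mean within-half-chain
    variance and B the between-half-chain variance (n * variance of half-chain
    means), R-hat = sqrt(((n-1)/n * W + B/n) / W).  Values near 1 indicate
    that the chain halves are indistinguishable, i.e. the chains mixed.
    Returns NaN (with a warning) when W is zero.
    """
    arr = _as_chains(draws)
    m, n = arr.shape
    if m < 2:
        raise ValueError("split_rhat requires at least 2 chains")
    if n < 4:
        raise ValueError("split_rhat requires chains of length >= 4")
    half = (n // 2) * 2
    halves = arr[:, :half].reshape(2 * m, half // 2)
    n_half = half // 2
    w = halves.var(axis=1, ddof=1).mean()
    if w == 0.0:
        warnings.warn("zero within-chain variance; split R-hat undefined", RuntimeWarning)
        return float("nan")
    b = n_half * halves.mean(axis=1).var(ddof=1)
    var_plus = (n_half - 1.0) / n_half * w + b / n_half
    return float(np.sqrt(var_plus / w))


def _autocov(x: np.ndarray) -> np.ndarray:
    """Biased (1/n) autocovariance of one chain via FFT."""
    n = len(x)
    xc = x - x.mean()
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size)
    acov = np.fft.irfft(f * np.conj(f), size)[:n].real / n
    return acov


def effective_sample_size(draws, cap_at_total: bool = False) -> float:
    """Autocorrelation-based effective sample size over multiple chains.

    Combines within-chain autocovariances with the between-chain variance
    (as in the multi-chain generalization of the autocorrelation-time
    estimator) and truncates the lag sum with Geyer's initial monotone
    positive sequence.  Set ``cap_at_total`` to clip super-efficient
    (negatively autocorrelated) results at the raw draw count, the convention
    used in the package's summary reports.
    """
    arr = _as_chains(draws)
    m, n = arr.shape
    if m < 2:
        raise ValueError("effective_sample_size requires at least 2 chains")
    acov = np.stack([_autocov(arr[c]) for c in range(m)])
    chain_var = arr.var(axis=1, ddof=1)
    w = chain_var.mean()
    if w == 0.0:
        warnings.warn("zero within-chain variance; ESS undefined", RuntimeWarning)
        return float("nan")
    # var_plus = (n-1)/n W + B/n with B = n*var(chain means, ddof=1)
    b = n * arr.mean(axis=1).var(ddof=1)
    var_plus = (n - 1.0) / n * w + b / n
    rho = 1.0 - (w - acov.mean(axis=0)) / var_plus
    rho[0] = 1.0
    # Geyer pairs: (rho_0+rho_1), (rho_2+rho_3), ...
    max_pairs = (len(rho) // 2) * 2
    pairs = rho[:max_pairs].reshape(-1, 2).sum(axis=1)
    # initial positive sequence
    pos = np.nonzero(pairs <= 0)[0]
    k = pos[0] if len(pos) else len(pairs)
    pairs = pairs[:k]
    # initial monotone sequence
    if len(pairs):
        pairs = np.minimum.accumulate(pairs)
    tau = max(-1.0 + 2.0 * pairs.sum(), 1.0 / (m * n))
    ess = m * n / tau
    if cap_at_total:
        ess = min(ess, float(m * n))
    return float(ess)
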