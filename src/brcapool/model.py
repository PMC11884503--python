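"""Densities and transforms of the hierarchical beta-binomial prevalence model.

Model
-----
Each cohort ``i`` has a latent true prevalence ``theta_i`` of pathogenic
somatic BRCA1/2 variants.  Prevalences are exchangeable across cohorts and
drawn from a Beta distribution parametrized by its mean ``mu`` and
concentration ``kappa``::

    theta_i ~ BetaProportion(mu, kappa) == Beta(mu*kappa, (1-mu)*kappa)
    P_i     ~ Binomial(N_i, theta_i)

with hyperpriors ``mu ~ Beta(1, 1)`` and ``kappa ~ Gamma(shape=1, rate=0.1)``
(an Exponential with mean 10; see PriorSpec).  Larger ``kappa`` concentrates
the cohort prevalences around ``mu`` (complete pooling in the limit), smaller
``kappa`` lets them disperse.

All densities are computed in log space through log-gamma/log-beta special
functions; the largest cohort (N=837) overflows naive factorials.  Boundary
values of ``theta``/``mu`` (0 or 1) are rejected, not clamped: the sampler and
oracle work on the open interval via logit/log transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .cohort_io import CohortTable

__all__ = [
    "PriorSpec",
    "HyperParams",
    "ParamVector",
    "UnconstrainedVector",
    "beta_proportion_logpdf",
    "log_prior",
    "log_likelihood",
    "log_joint",
    "to_unconstrained",
    "from_unconstrained",
    "log_jacobian",
    "beta_binomial_log_marginal",
]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperprior constants: Beta(mu_alpha, mu_beta) on mu, Gamma(kappa_shape,
    kappa_rate) on kappa (shape–rate convention).

    The default dispersion prior is Gamma(1, 0.1), i.e. Exponential with mean
    10: weakly informative, proper, and heavy enough in the tail to let the
    data place kappa in the tens when cohorts genuinely differ.
    """

    mu_alpha: float = 1.0
    mu_beta: float = 1.0
    kappa_shape: float = 1.0
    kappa_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("mu_alpha", "mu_beta", "kappa_shape", "kappa_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"PriorSpec.{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class HyperParams:
    """Population mean prevalence mu in (0,1) and concentration kappa > 0."""

    mu: float
    kappa: float

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < 1.0):
            raise ValueError(f"mu must lie in the open interval (0,1), got {self.mu}")
        if not (self.kappa > 0.0 and np.isfinite(self.kappa)):
            raise ValueError(f"kappa must be a positive finite real, got {self.kappa}")


@dataclass(frozen=True)
class ParamVector:
    """Full constrained parameter state: (mu, kappa, theta_1..theta_K)."""

    hyper: HyperParams
    thetas: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "thetas", tuple(float(t) for t in self.thetas))
        if len(self.thetas) < 1:
            raise ValueError("ParamVector needs at least one theta")
        for i, t in enumerate(self.thetas):
            if not (0.0 < t < 1.0):
                raise ValueError(f"theta[{i}] must lie in (0,1), got {t}")


@dataclass(frozen=True)
class UnconstrainedVector:
    """Bijective image of ParamVector: (logit mu, log kappa, logit theta_i)."""

    z_mu: float
    z_kappa: float
    z_thetas: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "z_thetas", tuple(float(z) for z in self.z_thetas))
        vals = (self.z_mu, self.z_kappa, *self.z_thetas)
        if not np.all(np.isfinite(vals)):
            raise ValueError("unconstrained coordinates must be finite")


def _check_prop(name: str, x) -> None:
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError(f"{name} must lie in the open interval (0,1)")


def beta_proportion_logpdf(x, mu, kappa):
    """Log density of BetaProportion(mu, kappa) = Beta(mu*kappa, (1-mu)*kappa) at x.

    Broadcasts over array arguments.
    """
    _check_prop("x", x)
    _check_prop("mu", mu)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be positive")
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    a = mu * kappa
    b = (1.0 - mu) * kappa
    out = (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - special.betaln(a, b)
    return out if out.ndim else float(out)


def log_prior(hyper: HyperParams, prior: PriorSpec = PriorSpec()) -> float:
    """Log hyperprior density: Beta on mu plus shape–rate Gamma on kappa."""
    mu, kappa = hyper.mu, hyper.kappa
    lp_mu = (
        (prior.mu_alpha - 1.0) * np.log(mu)
        + (prior.mu_beta - 1.0) * np.log1p(-mu)
        - special.betaln(prior.mu_alpha, prior.mu_beta)
    )
    lp_kappa = (
        prior.kappa_shape * np.log(prior.kappa_rate)
        - special.gammaln(prior.kappa_shape)
        + (prior.kappa_shape - 1.0) * np.log(kappa)
        - prior.kappa_rate * kappa
    )
    return float(lp_mu + lp_kappa)


def log_likelihood(table: CohortTable, thetas) -> float:
    """Sum of binomial log-pmfs log P(P_i | N_i, theta_i), constants included."""
    thetas = np.asarray(thetas, dtype=float)
    if thetas.shape != (len(table),):
        raise ValueError(
            f"expected {len(table)} thetas for {len(table)} cohorts, got shape {thetas.shape}"
        )
    _check_prop("thetas", thetas)
    n = np.asarray(table.n_tested, dtype=float)
    p = np.asarray(table.n_positive, dtype=float)
    log_comb = special.gammaln(n + 1) - special.gammaln(p + 1) - special.gammaln(n - p + 1)
    return float(np.sum(log_comb + p * np.log(thetas) + (n - p) * np.log1p(-thetas)))


def log_joint(params: ParamVector, table: CohortTable, prior: PriorSpec = PriorSpec()) -> float:
    """Log of the unnormalized posterior on the constrained scale."""
    if len(params.thetas) != len(table):
        raise ValueError("theta count does not match cohort count")
    hyper = params.hyper
    pop = np.sum(
        beta_proportion_logpdf(np.asarray(params.thetas), hyper.mu, hyper.kappa)
    )
    return log_prior(hyper, prior) + float(pop) + log_likelihood(table, params.thetas)


def to_unconstrained(params: ParamVector) -> UnconstrainedVector:
    return UnconstrainedVector(
        z_mu=float(special.logit(params.hyper.mu)),
        z_kappa=float(np.log(params.hyper.kappa)),
        z_thetas=tuple(float(special.logit(t)) for t in params.thetas),
    )


def from_unconstrained(z: UnconstrainedVector) -> ParamVector:
    return ParamVector(
        hyper=HyperParams(
            mu=float(special.expit(z.z_mu)), kappa=float(np.exp(z.z_kappa))
        ),
        thetas=tuple(float(special.expit(zz)) for zz in z.z_thetas),
    )


def _logit_log_jac(z: float) -> float:
    # d(expit)/dz = expit(z)*(1-expit(z)); log of it, stably
    return float(z - 2.0 * np.logaddexp(0.0, z))


def log_jacobian(z: UnconstrainedVector) -> float:
    """Log |det J| of the inverse transform (unconstrained -> constrained).

    Each logit coordinate contributes z - 2*log(1+e^z); the log coordinate for
    kappa contributes z_kappa itself.
    """
    total = _logit_log_jac(z.z_mu) + z.z_kappa
    total += sum(_logit_log_jac(zz) for zz in z.z_thetas)
    return float(total)


def beta_binomial_log_marginal(n, p, mu, kappa):
    """Log pmf of P after integrating theta ~ BetaProportion(mu, kappa) out of
    Binomial(n, theta):  log C(n,p) + log B(p+a, n-p+b) - log B(a, b) with
    a = mu*kappa, b = (1-mu)*kappa.  Broadcasts over array arguments.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > n):
        raise ValueError("require 0 <= p <= n")
    _check_prop("mu", mu)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be positive")
    mu = np.asarray(mu, dtype=float)
    a = mu * kappa
    b = (1.0 - mu) * kappa
    out = (
        special.gammaln(n + 1)
        - special.gammaln(p + 1)
        - special.gammaln(n - p + 1)
        + special.betaln(p + a, n - p + b)
        - special.betaln(a, b)
    )
    return out if out.ndim else float(out)
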