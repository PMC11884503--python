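"""Deterministic posterior by 2-D grid quadrature on (logit mu, log kappa).

Integrating each theta_i out of the likelihood analytically (the beta-binomial
marginal) collapses the posterior to two dimensions, which a fixed grid
resolves to high accuracy with no Monte Carlo error.  Conditional on (mu,
kappa) each theta_i is conjugate,

    theta_i | mu, kappa, data  ~  Beta(P_i + mu*kappa, N_i - P_i + (1-mu)*kappa),

so every theta_i posterior is an exact finite mixture of Beta distributions
over the grid nodes, and quantiles follow by monotone root finding on the
mixture CDF.  This module is the package's reference answer against which the
MCMC sampler is validated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special

from .cohort_io import CohortTable
from .model import PriorSpec, beta_binomial_log_marginal

__all__ = ["GridSpec", "GridPosterior", "grid_posterior", "hyper_quantile", "theta_quantile"]

# mixture components lighter than this fraction of the heaviest node carry no
# mass at double precision and are dropped from theta CDF evaluations
_PRUNE_REL = 1e-14


@dataclass(frozen=True)
class GridSpec:
    """Uniform quadrature grid on the unconstrained scale.

    Defaults span mu from expit(-9) ~ 1.2e-4 to expit(4) ~ 0.982 and kappa
    from e^-12 to e^9 ~ 8100, wide enough that posterior mass at the grid
    boundary is negligible for any plausible cohort table under the default
    priors.
    """

    z_mu_range: tuple[float, float] = (-9.0, 4.0)
    z_kappa_range: tuple[float, float] = (-12.0, 9.0)
    n_mu: int = 400
    n_kappa: int = 400

    def __post_init__(self) -> None:
        for name in ("z_mu_range", "z_kappa_range"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"GridSpec.{name} must be a finite increasing interval")
        if self.n_mu < 50 or self.n_kappa < 50:
            raise ValueError("GridSpec node counts must be >= 50")


@dataclass(frozen=True)
class GridPosterior:
    """Normalized joint posterior weights of (mu, kappa) on a fixed grid."""

    mu: np.ndarray            # (n_mu,) node values on (0,1)
    kappa: np.ndarray         # (n_kappa,) node values on (0,inf)
    weights: np.ndarray       # (n_mu, n_kappa), nonnegative, sums to 1
    log_norm: float           # log of the marginal likelihood estimate
    table: CohortTable | None  # None for a prior-only (no-data) posterior
    boundary_mass: float      # total weight on the outermost grid ring
    grid: GridSpec = field(default=GridSpec())

    def marginal(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(node values, marginal weights) for 'mu' or 'kappa'."""
        if which == "mu":
            return self.mu, self.weights.sum(axis=1)
        if which == "kappa":
            return self.kappa, self.weights.sum(axis=0)
        raise ValueError(f"unknown hyperparameter {which!r}; expected 'mu' or 'kappa'")

    def to_frame(self) -> pd.DataFrame:
        mu_g, ka_g = np.meshgrid(self.mu, self.kappa, indexing="ij")
        return pd.DataFrame(
            {"mu": mu_g.ravel(), "kappa": ka_g.ravel(), "weight": self.weights.ravel()}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.empty_like(x)
    w[1:-1] = (x[2:] - x[:-2]) / 2.0
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    return w


def grid_posterior(
    table: CohortTable | None,
    prior: PriorSpec = PriorSpec(),
    grid: GridSpec = GridSpec(),
) -> GridPosterior:
    """Quadrature posterior of (mu, kappa) given the cohort counts.

    ``table=None`` computes the no-data posterior (the hyperprior itself on
    the grid), the degenerate limit used to validate the quadrature.

    At each node the unnormalized log weight is the log hyperprior plus the
    sum of beta-binomial log marginals over cohorts, plus the Jacobian of the
    (logit, log) grid parametrization; trapezoid cell masses convert densities
    to weights, normalized over the grid.  A warning is raised if more than
    1e-6 of the mass sits on the outermost grid ring (posterior leaking
    off-grid).
    """
    z_mu = np.linspace(*grid.z_mu_range, grid.n_mu)
    z_ka = np.linspace(*grid.z_kappa_range, grid.n_kappa)
    mu = special.expit(z_mu)
    kappa = np.exp(z_ka)

    mu_g, ka_g = np.meshgrid(mu, kappa, indexing="ij")
    log_w = (
        (prior.mu_alpha - 1.0) * np.log(mu_g)
        + (prior.mu_beta - 1.0) * np.log1p(-mu_g)
        - special.betaln(prior.mu_alpha, prior.mu_beta)
        + prior.kappa_shape * np.log(prior.kappa_rate)
        - special.gammaln(prior.kappa_shape)
        + (prior.kappa_shape - 1.0) * np.log(ka_g)
        - prior.kappa_rate * ka_g
    )
    if table is not None:
        for n, p in zip(table.n_tested, table.n_positive):
            log_w += beta_binomial_log_marginal(n, p, mu_g, ka_g)
    # Jacobian of (mu, kappa) = (expit(z_mu), exp(z_kappa))
    log_w += np.log(mu_g) + np.log1p(-mu_g) + np.log(ka_g)

    cell = np.outer(_trapezoid_weights(z_mu), _trapezoid_weights(z_ka))
    shift = log_w.max()
    raw = np.exp(log_w - shift) * cell
    total = raw.sum()
    log_norm = float(shift + np.log(total))
    weights = raw / total

    ring = (
        weights[0, :].sum()
        + weights[-1, :].sum()
        + weights[1:-1, 0].sum()
        + weights[1:-1, -1].sum()
    )
    if ring > 1e-6:
        warnings.warn(
            f"grid posterior has boundary mass {ring:.2e} > 1e-6; widen GridSpec ranges",
            RuntimeWarning,
            stacklevel=2,
        )
    return GridPosterior(
        mu=mu,
        kappa=kappa,
        weights=weights,
        log_norm=log_norm,
        table=table,
        boundary_mass=float(ring),
        grid=grid,
    )


def hyper_quantile(gp: GridPosterior, which: str, q) -> float | np.ndarray:
    """Quantile of the marginal grid posterior of mu or kappa.

    The discrete marginal is read as a CDF with each node's mass centered on
    it (midpoint rule) and linearly interpolated between nodes; monotone in q.
    """
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q_arr <= 0) | (q_arr >= 1)):
        raise ValueError("quantile level q must lie in (0,1)")
    vals, w = gp.marginal(which)
    cdf = np.cumsum(w) - w / 2.0
    out = np.interp(q_arr, cdf, vals)
    return out if np.ndim(q) else float(out[0])


def _mixture_components(gp: GridPosterior, cohort_index: int):
    if gp.table is None:
        raise ValueError("theta quantiles are undefined for a prior-only grid posterior")
    rec = gp.table[cohort_index]
    mu_g, ka_g = np.meshgrid(gp.mu, gp.kappa, indexing="ij")
    w = gp.weights.ravel()
    keep = w > w.max() * _PRUNE_REL
    w = w[keep]
    a = rec.n_positive + (mu_g * ka_g).ravel()[keep]
    b = (rec.n_tested - rec.n_positive) + ((1.0 - mu_g) * ka_g).ravel()[keep]
    return w / w.sum(), a, b


def theta_quantile(gp: GridPosterior, cohort_index: int, q) -> float | np.ndarray:
    """Quantile of cohort ``cohort_index``'s prevalence posterior.

    The posterior of theta_i is the weight-mixture of conjugate Beta
    distributions over grid nodes; the quantile is found by bracketed root
    finding on the monotone mixture CDF to 1e-10.
    """
    if gp.table is None:
        raise ValueError("theta quantiles are undefined for a prior-only grid posterior")
    if not 0 <= cohort_index < len(gp.table):
        raise IndexError(f"cohort_index {cohort_index} out of range for {len(gp.table)} cohorts")
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q_arr <= 0) | (q_arr >= 1)):
        raise ValueError("quantile level q must lie in (0,1)")
    w, a, b = _mixture_components(gp, cohort_index)
    eps = 1e-12

    def cdf(x: float) -> float:
        return float(w @ special.betainc(a, b, x))

    f_lo, f_hi = cdf(eps), cdf(1.0 - eps)
    out = np.empty_like(q_arr)
    for j, qq in enumerate(q_arr):
        # mixtures with shape parameters << 1 can hold mass beyond the
        # bracket; the quantile is then clamped to the bracket edge
        if f_lo >= qq:
            out[j] = eps
        elif f_hi <= qq:
            out[j] = 1.0 - eps
        else:
            out[j] = optimize.brentq(lambda x: cdf(x) - qq, eps, 1.0 - eps, xtol=1e-10)
    return out if np.ndim(q) else float(out[0])
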