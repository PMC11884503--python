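"""Exact no-pooling ("unadjusted") per-cohort posteriors.

Under the independent model each cohort's prevalence rho_i has a
Beta(mu_alpha, mu_beta) prior (Beta(1,1) by default) and a binomial
likelihood, so the posterior is Beta(mu_alpha + P_i, mu_beta + N_i - P_i) in
closed form — no sampling needed.  These are the comparators against which
the hierarchical ("adjusted") estimates show their shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_io import CohortRecord, CohortTable
from .model import PriorSpec

__all__ = ["BetaPosterior", "unadjusted_posterior", "unadjusted_posteriors", "beta_quantile"]


@dataclass(frozen=True)
class BetaPosterior:
    shape1: float
    shape2: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.shape1 > 0 and self.shape2 > 0):
            raise ValueError(
                f"Beta shapes must be positive, got ({self.shape1}, {self.shape2})"
            )


def unadjusted_posterior(record: CohortRecord, prior: PriorSpec = PriorSpec()) -> BetaPosterior:
    """Conjugate posterior Beta(mu_alpha + P, mu_beta + N - P) for one cohort."""
    return BetaPosterior(
        shape1=prior.mu_alpha + record.n_positive,
        shape2=prior.mu_beta + record.n_tested - record.n_positive,
        label=record.label,
    )


def unadjusted_posteriors(table: CohortTable, prior: PriorSpec = PriorSpec()) -> list[BetaPosterior]:
    return [unadjusted_posterior(r, prior) for r in table]


def beta_quantile(post: BetaPosterior, q) -> float | np.ndarray:
    """Posterior quantile via the inverse regularized incomplete beta function."""
    q_arr = np.asarray(q, dtype=float)
    if np.any((q_arr <= 0) | (q_arr >= 1)):
        raise ValueError("quantile level q must lie in (0,1)")
    out = stats.beta.ppf(q_arr, post.shape1, post.shape2)
    return out if out.ndim else float(out)
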