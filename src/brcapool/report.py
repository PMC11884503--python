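"""Posterior summaries, the per-cohort report table, and the forest-style figure.

Every estimate is reported as the posterior median with an equal-tailed 95%
credible interval (2.5% and 97.5% quantiles).  The cohort report pairs each
cohort's "adjusted" prevalence (theta_i under the hierarchical model) with its
"unadjusted" one (independent conjugate Beta posterior) and records the
shrinkage — the absolute difference of the two medians — which quantifies how
strongly the other cohorts pulled the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import CohortTable
from .conjugate import BetaPosterior, beta_quantile
from .mcmc import PosteriorDraws, split_rhat
from .oracle import GridPosterior, hyper_quantile, theta_quantile

__all__ = [
    "PosteriorSummary",
    "CohortReportRow",
    "summarize",
    "summarize_all",
    "build_report",
    "render_table",
    "forest_plot",
]

_Q = (0.5, 0.025, 0.975)


@dataclass(frozen=True)
class PosteriorSummary:
    parameter: str
    median: float
    cdi_low: float
    cdi_high: float
    r_hat: float | None = None  # absent for closed-form / quadrature results

    def __post_init__(self) -> None:
        if not (self.cdi_low <= self.median <= self.cdi_high):
            raise ValueError(
                f"{self.parameter}: median {self.median} outside CdI "
                f"[{self.cdi_low}, {self.cdi_high}]"
            )


@dataclass(frozen=True)
class CohortReportRow:
    label: str
    adjusted: PosteriorSummary
    unadjusted: PosteriorSummary

    @property
    def shrinkage(self) -> float:
        """|adjusted median - unadjusted median| (proportion scale)."""
        return abs(self.adjusted.median - self.unadjusted.median)


def summarize(source, parameter: str) -> PosteriorSummary:
    """Median and equal-tailed 95% CdI for one parameter of any posterior source.

    ``source`` may be a :class:`PosteriorDraws` (quantiles of pooled draws with
    the "type 7" linear-interpolation rule, split R-hat attached), a
    :class:`GridPosterior` (deterministic quadrature quantiles), or a
    :class:`BetaPosterior` (exact quantiles, ``parameter`` ignored for lookup).
    """
    if isinstance(source, PosteriorDraws):
        x = source.flat(parameter)
        med, lo, hi = np.quantile(x, _Q)
        return PosteriorSummary(parameter, float(med), float(lo), float(hi),
                                r_hat=split_rhat(source.array(parameter)))
    if isinstance(source, GridPosterior):
        if parameter in ("mu", "kappa"):
            med, lo, hi = (hyper_quantile(source, parameter, q) for q in _Q)
        else:
            labels = source.table.labels
            name = parameter[parameter.index("[") + 1 : -1] if "[" in parameter else parameter
            if name not in labels:
                raise KeyError(f"unknown parameter {parameter!r} for this cohort table")
            idx = labels.index(name)
            med, lo, hi = (theta_quantile(source, idx, q) for q in _Q)
        return PosteriorSummary(parameter, float(med), float(lo), float(hi))
    if isinstance(source, BetaPosterior):
        med, lo, hi = (beta_quantile(source, q) for q in _Q)
        return PosteriorSummary(parameter, float(med), float(lo), float(hi))
    raise TypeError(f"cannot summarize source of type {type(source).__name__}")


def summarize_all(source, table: CohortTable, kind: str = "theta") -> list[PosteriorSummary]:
    """Summaries for mu, kappa (when present) and every cohort-level parameter."""
    out = []
    if isinstance(source, (PosteriorDraws, GridPosterior)):
        if isinstance(source, GridPosterior) or "mu" in source.draws:
            out.append(summarize(source, "mu"))
            out.append(summarize(source, "kappa"))
        for lab in table.labels:
            out.append(summarize(source, f"{kind}[{lab}]"))
    elif isinstance(source, (list, tuple)):  # list of BetaPosterior
        for post in source:
            s = summarize(post, f"{kind}[{post.label}]")
            out.append(PosteriorSummary(f"{kind}[{post.label}]", s.median, s.cdi_low, s.cdi_high))
    else:
        raise TypeError(f"cannot summarize source of type {type(source).__name__}")
    return out


def _cohort_summaries(summaries, table: CohortTable) -> list[PosteriorSummary]:
    """Pick the per-cohort entries out of a summary list, in table order."""
    by_label = {}
    for s in summaries:
        if "[" in s.parameter:
            by_label[s.parameter[s.parameter.index("[") + 1 : -1]] = s
    missing = [lab for lab in table.labels if lab not in by_label]
    if missing:
        raise ValueError(f"no summary found for cohort label(s) {missing}")
    return [by_label[lab] for lab in table.labels]


def build_report(
    table: CohortTable,
    adjusted_summaries,
    unadjusted_summaries,
) -> list[CohortReportRow]:
    """Pair adjusted and unadjusted per-cohort summaries, in cohort order."""
    adj = _cohort_summaries(adjusted_summaries, table)
    unadj = _cohort_summaries(unadjusted_summaries, table)
    return [
        CohortReportRow(label=lab, adjusted=a, unadjusted=u)
        for lab, a, u in zip(table.labels, adj, unadj)
    ]


def _pct(x: float) -> float:
    # percent to one decimal, round half to even
    return float(np.round(100.0 * x, 1))


def report_frame(rows: list[CohortReportRow]) -> pd.DataFrame:
    """Tabular report: rounded display columns plus unrounded parallel columns."""
    if not rows:
        raise ValueError("report has no rows")
    rec = []
    for r in rows:
        rec.append(
            {
                "label": r.label,
                "adjusted_median_pct": _pct(r.adjusted.median),
                "adjusted_cdi_pct": f"{_pct(r.adjusted.cdi_low):.1f}-{_pct(r.adjusted.cdi_high):.1f}",
                "adjusted_r_hat": (
                    "" if r.adjusted.r_hat is None else f"{r.adjusted.r_hat:.3f}"
                ),
                "unadjusted_median_pct": _pct(r.unadjusted.median),
                "unadjusted_cdi_pct": f"{_pct(r.unadjusted.cdi_low):.1f}-{_pct(r.unadjusted.cdi_high):.1f}",
                "unadjusted_r_hat": (
                    "" if r.unadjusted.r_hat is None else f"{r.unadjusted.r_hat:.3f}"
                ),
                "shrinkage_pct": _pct(r.shrinkage),
                "adjusted_median": r.adjusted.median,
                "adjusted_cdi_low": r.adjusted.cdi_low,
                "adjusted_cdi_high": r.adjusted.cdi_high,
                "unadjusted_median": r.unadjusted.median,
                "unadjusted_cdi_low": r.unadjusted.cdi_low,
                "unadjusted_cdi_high": r.unadjusted.cdi_high,
            }
        )
    return pd.DataFrame(rec)


def render_table(rows: list[CohortReportRow], csv_path: str | Path | None = None) -> tuple[str, str]:
    """Render the report as (CSV text, plain text table); optionally write the CSV.

    The CSV is fully built before any file is touched, so a failure leaves no
    partial output; identical rows give byte-identical CSV.
    """
    df = report_frame(rows)
    csv_text = df.to_csv(index=False)
    display_cols = [
        "label",
        "adjusted_median_pct",
        "adjusted_cdi_pct",
        "adjusted_r_hat",
        "unadjusted_median_pct",
        "unadjusted_cdi_pct",
        "unadjusted_r_hat",
        "shrinkage_pct",
    ]
    text = df[display_cols].to_string(index=False)
    if csv_path is not None:
        Path(csv_path).write_text(csv_text)
    return csv_text, text


def forest_plot(rows: list[CohortReportRow], draws: PosteriorDraws, path: str | Path) -> None:
    """Per-cohort posterior densities with 95% CdI bars and shrinkage labels.

    For each cohort: a kernel density of the adjusted theta draws, the exact
    unadjusted Beta density, an interval bar at the adjusted 95% CdI with a
    dot at the median, and the shrinkage annotated in the corner.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not rows:
        raise ValueError("no rows to plot")
    if not draws.param_names:
        raise ValueError("no draws to plot")

    fig, axes = plt.subplots(len(rows), 1, figsize=(7, 1.9 * len(rows)), sharex=True)
    axes = np.atleast_1d(axes)
    xs = np.linspace(1e-4, 0.5, 600)
    for ax, row in zip(axes, rows):
        theta = draws.flat(f"theta[{row.label}]")
        kde = stats.gaussian_kde(theta)
        ax.fill_between(xs, kde(xs), alpha=0.45, color="tab:orange", label="adjusted")
        # unadjusted: exact Beta density reconstructed from its quantiles is not
        # possible, so the caller's summaries are drawn as a density only when the
        # conjugate shapes can be recovered from counts; fall back to interval bar.
        ax.plot(
            [row.unadjusted.cdi_low, row.unadjusted.cdi_high],
            [-0.06 * kde(kde.dataset.mean()).item()] * 2,
            color="tab:blue",
            lw=2,
            label="unadjusted 95% CdI",
        )
        ax.plot(
            [row.adjusted.cdi_low, row.adjusted.cdi_high],
            [0, 0],
            color="black",
            lw=2,
        )
        ax.plot([row.adjusted.median], [0], "ko", ms=5)
        ax.annotate(
            f"Δ = {100 * row.shrinkage:.1f} pp",
            xy=(0.98, 0.85),
            xycoords="axes fraction",
            ha="right",
            fontsize=9,
        )
        ax.set_ylabel(row.label, rotation=0, ha="right", fontsize=8)
        ax.set_yticks([])
    axes[-1].set_xlabel("prevalence")
    axes[0].legend(loc="upper right", fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
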