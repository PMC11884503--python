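"""Cohort count tables: validated containers, CSV I/O, and the bundled study data.

A cohort is a group of metastatic prostate-cancer patients whose tumors were
somatically tested for pathogenic BRCA1/2 variants.  The model consumes only
the per-cohort counts: patients tested (``n_tested``) and patients positive
(``n_positive``).  Row order is significant — it defines the parameter index
``i`` of each cohort's prevalence theta_i throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "CohortRecord",
    "CohortTable",
    "CohortValidationError",
    "read_cohort_table",
    "write_cohort_table",
    "paper_cohorts",
]

REQUIRED_COLUMNS = ("label", "n_tested", "n_positive")


class CohortValidationError(ValueError):
    """A cohort table violates a structural invariant."""


@dataclass(frozen=True)
class CohortRecord:
    """Counts for one cohort: ``n_positive`` of ``n_tested`` patients positive."""

    label: str
    n_tested: int
    n_positive: int

    def __post_init__(self) -> None:
        if not isinstance(self.n_tested, int) or not isinstance(self.n_positive, int):
            raise CohortValidationError(
                f"cohort {self.label!r}: counts must be integers, got "
                f"n_tested={self.n_tested!r}, n_positive={self.n_positive!r}"
            )
        if self.n_tested < 1:
            raise CohortValidationError(
                f"cohort {self.label!r}: n_tested must be >= 1, got {self.n_tested}"
            )
        if self.n_positive < 0:
            raise CohortValidationError(
                f"cohort {self.label!r}: n_positive must be >= 0, got {self.n_positive}"
            )
        if self.n_positive > self.n_tested:
            raise CohortValidationError(
                f"cohort {self.label!r}: n_positive exceeds n_tested "
                f"({self.n_positive} > {self.n_tested})"
            )


@dataclass(frozen=True)
class CohortTable:
    """Ordered collection of :class:`CohortRecord`; order defines index ``i``."""

    records: tuple[CohortRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) < 1:
            raise CohortValidationError("cohort table must contain at least one record")
        labels = [r.label for r in self.records]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise CohortValidationError(f"duplicate cohort labels: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> CohortRecord:
        return self.records[i]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def n_tested(self) -> list[int]:
        return [r.n_tested for r in self.records]

    @property
    def n_positive(self) -> list[int]:
        return [r.n_positive for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "n_tested": self.n_tested,
                "n_positive": self.n_positive,
            }
        )


def _table_from_frame(df: pd.DataFrame, source: str) -> CohortTable:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(
            f"{source}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        label = str(getattr(row, "label"))
        raw_n = getattr(row, "n_tested")
        raw_p = getattr(row, "n_positive")
        try:
            n, p = int(raw_n), int(raw_p)
        except (TypeError, ValueError) as exc:
            raise CohortValidationError(
                f"{source}: cohort {label!r}: non-integer counts "
                f"(n_tested={raw_n!r}, n_positive={raw_p!r})"
            ) from exc
        if float(raw_n) != n or float(raw_p) != p:
            raise CohortValidationError(
                f"{source}: cohort {label!r}: counts must be whole numbers "
                f"(n_tested={raw_n!r}, n_positive={raw_p!r})"
            )
        records.append(CohortRecord(label=label, n_tested=n, n_positive=p))
    return CohortTable(records=tuple(records))


def read_cohort_table(path: str | Path) -> CohortTable:
    """Read a cohort table from a headered CSV with columns label/n_tested/n_positive.

    Extra columns (e.g. clinical metadata such as median age) are ignored.
    Row order is preserved and defines the cohort index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort table not found: {path}")
    # keep_default_na=False: labels like "NA" are labels, not missing values
    df = pd.read_csv(path, keep_default_na=False)
    return _table_from_frame(df, source=str(path))


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    """Write ``table`` as CSV such that a subsequent read round-trips exactly."""
    table.to_frame().to_csv(path, index=False)


def paper_cohorts() -> CohortTable:
    """The seven published cohorts bundled with the package, in table order.

    Six cohorts come from earlier universal-somatic-testing studies; the
    seventh (Barroso 2024, 0 positives of 42 tested) is the Portuguese cohort
    whose prevalence the hierarchical model is designed to stabilize.
    """
    with resources.as_file(
        resources.files("brcapool.data").joinpath("paper_cohorts.csv")
    ) as p:
        return read_cohort_table(p)
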