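"""Case/non-case construction: exclusion filters and 2x2 contingency tables.

In a case/non-case (disproportionality) design, "cases" are the reports
mentioning the reaction of interest and "non-cases" are all other reports in
the same database; exposure is contrasted *within* reports.  This module
provides the study's exclusion filters (applied before the adjusted
analyses, not before the crude whole-database screen) and the bookkeeping
that turns exposure/case predicates into a/b/c/d cell counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dictionaries import DrugCatalog, TermDictionary
from .report_io import Dataset, Report

__all__ = [
    "ContingencyTable",
    "ExclusionCriteria",
    "ExclusionLog",
    "is_case",
    "case_flags",
    "apply_exclusions",
    "build_table",
    "build_table_from_flags",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 case/non-case table.

    a: exposed cases, b: exposed non-cases, c: unexposed cases,
    d: unexposed non-cases.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    def transposed(self) -> "ContingencyTable":
        """Swap the exposure and case roles (b <-> c)."""
        return ContingencyTable(self.a, self.c, self.b, self.d)

    def rows_swapped(self) -> "ContingencyTable":
        """Swap the exposed and unexposed rows (a,b <-> c,d)."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


def is_case(report: Report, subtype: str, dictionary: TermDictionary) -> bool:
    """True iff the report's reactions intersect the subtype's PT set.

    A report can be a case for several subtypes at once; for any single
    subtype every other report — including cases of other subtypes — is a
    non-case.
    """
    return bool(report.reactions_casefolded() & dictionary.terms_casefolded(subtype))


def case_flags(
    dataset: Dataset, subtype: str, dictionary: TermDictionary
) -> np.ndarray:
    """Vectorized :func:`is_case` over a dataset (boolean array)."""
    terms = dictionary.terms_casefolded(subtype)
    return np.fromiter(
        (bool(r.reactions_casefolded() & terms) for r in dataset),
        dtype=bool,
        count=len(dataset),
    )


@dataclass(frozen=True)
class ExclusionCriteria:
    """Report-level exclusion rules for the adjusted analyses.

    The adjusted logistic models require complete covariates, so reports
    with missing age or sex are dropped; reports listing more than
    ``max_antidepressants_per_report`` study antidepressants are dropped so
    each report carries a single, unambiguous exposure; implausible
    ("outlying") ages are dropped — report quality below age 5 is
    unreliable in spontaneous-report systems and 110 is used as the upper
    plausibility bound.  Both bounds are configurable.
    """

    require_age: bool = True
    require_sex: bool = True
    min_age: float = 5.0
    max_age: float = 110.0
    max_antidepressants_per_report: int = 1
    year_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.min_age < self.max_age:
            raise ValueError("min_age must be < max_age")
        if self.max_antidepressants_per_report < 1:
            raise ValueError("max_antidepressants_per_report must be >= 1")
        if self.year_range is not None and self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range start must be <= end")

    @classmethod
    def inactive(cls) -> "ExclusionCriteria":
        """Criteria that exclude nothing (identity filter)."""
        return cls(
            require_age=False,
            require_sex=False,
            min_age=0.0,
            max_age=math.inf,
            max_antidepressants_per_report=10**9,
            year_range=None,
        )


#: Fixed application order; the per-step counts in the log depend on it and
#: the order is part of the contract.
EXCLUSION_ORDER = (
    "year_range",
    "missing_age",
    "outlying_age",
    "missing_sex",
    "polytherapy",
)


@dataclass
class ExclusionLog:
    """Per-criterion removal counts under the fixed sequential order."""

    n_input: int
    n_output: int
    removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert sum(self.removed.values()) == self.n_input - self.n_output

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": list(self.removed),
                "removed": list(self.removed.values()),
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def apply_exclusions(
    dataset: Dataset, criteria: ExclusionCriteria, catalog: DrugCatalog
) -> tuple[Dataset, ExclusionLog]:
    """Filter ``dataset`` sequentially by the active criteria.

    Steps, in order: year range -> missing age -> outlying age -> missing
    sex -> antidepressant polytherapy.  A report survives iff it passes
    every active criterion; the log attributes each removal to the first
    step that rejects it.  Idempotent: re-applying the same criteria to the
    output removes nothing.
    """
    ads = catalog.antidepressants
    removed = {step: 0 for step in EXCLUSION_ORDER}
    kept: list[Report] = []
    for r in dataset:
        if criteria.year_range is not None and not (
            criteria.year_range[0] <= r.year <= criteria.year_range[1]
        ):
            removed["year_range"] += 1
            continue
        if r.age is None:
            if criteria.require_age:
                removed["missing_age"] += 1
                continue
        elif not (criteria.min_age <= r.age <= criteria.max_age):
            removed["outlying_age"] += 1
            continue
        if criteria.require_sex and r.sex == "unknown":
            removed["missing_sex"] += 1
            continue
        if len(r.drugs_casefolded() & ads) > criteria.max_antidepressants_per_report:
            removed["polytherapy"] += 1
            continue
        kept.append(r)
    out = Dataset(reports=kept, provenance=dataset.provenance)
    return out, ExclusionLog(n_input=len(dataset), n_output=len(out), removed=removed)


def build_table(
    dataset: Dataset,
    exposed: Callable[[Report], bool],
    case: Callable[[Report], bool],
) -> ContingencyTable:
    """Count every report exactly once into a/b/c/d by the two predicates."""
    exp = np.fromiter((bool(exposed(r)) for r in dataset), dtype=bool, count=len(dataset))
    cas = np.fromiter((bool(case(r)) for r in dataset), dtype=bool, count=len(dataset))
    return build_table_from_flags(exp, cas)


def build_table_from_flags(
    exposed: np.ndarray | Sequence[bool], case: np.ndarray | Sequence[bool]
) -> ContingencyTable:
    """Contingency table from precomputed boolean exposure/case arrays."""
    exposed = np.asarray(exposed, dtype=bool)
    case = np.asarray(case, dtype=bool)
    if exposed.shape != case.shape:
        raise ValueError("exposure and case flags must have the same length")
    a = int(np.sum(exposed & case))
    b = int(np.sum(exposed & ~case))
    c = int(np.sum(~exposed & case))
    d = int(np.sum(~exposed & ~case))
    return ContingencyTable(a, b, c, d)
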