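"""Crude reporting odds ratios, Bonferroni control, significance flagging.

The reporting odds ratio (ROR) for a drug–event pair is the odds of exposure
among case reports divided by the odds of exposure among non-case reports:
``(a/c) / (b/d) = ad/bc`` for a 2x2 case/non-case table.  Confidence
intervals and p-values use the Wald construction on the log-odds scale —
``exp(ln ROR ± z * sqrt(1/a + 1/b + 1/c + 1/d))`` — with no continuity
correction; a table with any empty cell yields an *undefined* result (the
estimate is withheld rather than Haldane–Anscombe-corrected).

The screening significance rule combines three conditions: ROR > 1, Wald
p-value below a Bonferroni-adjusted alpha, and at least ``min_cases``
exposed cases (disproportionality estimates on a handful of reports are not
interpretable as signals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .case_noncase import ContingencyTable, build_table_from_flags, case_flags
from .dictionaries import DrugCatalog, TermDictionary
from .report_io import Dataset

__all__ = [
    "RorResult",
    "crude_ror",
    "bonferroni_alpha",
    "flag_significance",
    "whole_database_screen",
]


@dataclass(frozen=True)
class RorResult:
    """Point estimate and inference for one exposure/outcome comparison.

    ``estimate`` is ``None`` when the comparison is undefined (an empty
    cell, a failed fit); CI bounds and the p-value are then ``None``/NaN.
    """

    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float
    n_exposed_cases: int
    method: str  # "crude" | "adjusted"
    significant: bool = False

    @property
    def defined(self) -> bool:
        return self.estimate is not None

    def __post_init__(self) -> None:
        if self.defined:
            if not (0 < self.ci_low <= self.estimate <= self.ci_high):  # type: ignore[operator]
                raise ValueError(
                    f"CI must bracket the estimate: {self.ci_low}, "
                    f"{self.estimate}, {self.ci_high}"
                )


def _undefined(n_exposed_cases: int, method: str) -> RorResult:
    return RorResult(
        estimate=None,
        ci_low=None,
        ci_high=None,
        p_value=float("nan"),
        n_exposed_cases=n_exposed_cases,
        method=method,
        significant=False,
    )


def crude_ror(table: ContingencyTable, confidence: float = 0.95) -> RorResult:
    """Crude ROR with Wald CI and two-sided Wald p-value.

    estimate = ad/bc; on the log scale the standard error is
    sqrt(1/a + 1/b + 1/c + 1/d) and the CI is exp(ln ROR ± z·SE) with z the
    standard-normal quantile for ``confidence``.  Undefined (estimate
    withheld) when any cell is zero.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return _undefined(a, "crude")
    log_or = math.log(a) + math.log(d) - math.log(b) - math.log(c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(norm.ppf(0.5 + confidence / 2))
    p = float(2 * norm.sf(abs(log_or) / se))
    return RorResult(
        estimate=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=p,
        n_exposed_cases=a,
        method="crude",
    )


def bonferroni_alpha(
    n_comparisons: int, family_alpha: float = 0.05, rounding: int | None = None
) -> float:
    """Bonferroni-adjusted per-comparison alpha: ``family_alpha / n``.

    ``rounding`` optionally rounds the threshold to that many decimal
    places (e.g. 0.05/58 = 0.000862 rounds to 0.001 at 3 d.p.), matching
    the common practice of quoting a rounded working threshold.
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    alpha = family_alpha / n_comparisons
    if rounding is not None:
        alpha = round(alpha, rounding)
    return alpha


def flag_significance(
    result: RorResult, alpha: float, min_cases: int = 10
) -> RorResult:
    """Return ``result`` with the significance flag set per the screening
    rule: estimate defined and > 1, p-value < alpha, and at least
    ``min_cases`` exposed cases.  All other fields are unchanged."""
    sig = (
        result.defined
        and result.estimate > 1  # type: ignore[operator]
        and result.p_value < alpha
        and result.n_exposed_cases >= min_cases
    )
    return replace(result, significant=bool(sig))


def whole_database_screen(
    dataset: Dataset,
    catalog: DrugCatalog,
    dictionary: TermDictionary,
    confidence: float = 0.95,
    alpha: float = 0.001,
    min_cases: int = 10,
) -> pd.DataFrame:
    """Crude ROR of antidepressant exposure for every subtype.

    For each subtype in ``dictionary``: exposure = the report lists at
    least one catalog antidepressant; case = the report matches the
    subtype's PT set; comparator = every other report in the dataset.  No
    exclusion filtering is applied — the whole-database screen runs on the
    full dataset, mirroring a database-wide crude query.

    Returns a DataFrame with one row per subtype: the a/b/c/d cells, the
    estimate, CI bounds, p-value and significance flag (``alpha`` and
    ``min_cases`` feed :func:`flag_significance`).
    """
    ads = catalog.antidepressants
    exposed = np.fromiter(
        (bool(r.drugs_casefolded() & ads) for r in dataset),
        dtype=bool,
        count=len(dataset),
    )
    rows = []
    for subtype in dictionary.names():
        cases = case_flags(dataset, subtype, dictionary)
        table = build_table_from_flags(exposed, cases)
        res = flag_significance(crude_ror(table, confidence), alpha, min_cases)
        rows.append(
            {
                "subtype": subtype,
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "ror": res.estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "significant": res.significant,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
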