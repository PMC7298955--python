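"""Adjusted reporting odds ratios via logistic regression.

The adjusted ROR (aROR) is the exponentiated exposure coefficient from a
maximum-likelihood logistic regression of the case indicator on an exposure
indicator plus confounders.  The confounder set used throughout is: age,
sex, presence of a co-medication able to induce movement disorders, and
presence of a co-medication used to treat movement disorders.  One model is
fitted per exposure (each drug or class against its comparator), i.e. the
comparisons are a family of single-exposure adjusted models, not one joint
multi-drug model.

Inputs to these functions are expected to have passed
:func:`pvror.case_noncase.apply_exclusions` (complete age/sex, single
antidepressant per report); the functions do not re-filter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .case_noncase import build_table_from_flags, case_flags
from .dictionaries import CLASSES, DrugCatalog, TermDictionary
from .disproportionality import RorResult, flag_significance
from .report_io import Dataset

__all__ = [
    "AnalysisDesign",
    "FitDiagnostics",
    "fit_adjusted_ror",
    "class_comparison",
    "drug_comparison",
    "sensitivity_restricted_period",
    "results_to_wide",
]

DEFAULT_COVARIATES = ("age", "sex", "inducer", "treater")
_COVARIATE_DOMAIN = frozenset(DEFAULT_COVARIATES)

#: Age-band edges (years) for the categorical age coding option.
AGE_BAND_EDGES = (18.0, 45.0, 65.0, 75.0)


@dataclass(frozen=True)
class AnalysisDesign:
    """Specification of one adjusted comparison.

    ``exposure`` is a string spec: ``"drug:<code>"`` (one antidepressant
    against all other reports in the analyzed dataset, i.e. the other
    antidepressants after the single-antidepressant exclusion),
    ``"class:<TCA|SRI|MAOI|OTHER>"`` (one class against the other three),
    or ``"any_antidepressant"`` (any catalog antidepressant against
    unexposed reports, for whole-database-style datasets).

    ``age_coding`` selects continuous age in years (default) or the
    demographic age bands as indicator categories.
    """

    outcome_subtype: str
    exposure: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    alpha: float = 0.001
    min_cases: int = 10
    confidence: float = 0.95
    age_coding: str = "continuous"

    def __post_init__(self) -> None:
        bad = set(self.covariates) - _COVARIATE_DOMAIN
        if bad:
            raise ValueError(f"unknown covariate(s): {sorted(bad)}")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("covariates must not repeat")
        if self.age_coding not in ("continuous", "bands"):
            raise ValueError("age_coding must be 'continuous' or 'bands'")
        kind, _, rest = self.exposure.partition(":")
        if kind not in ("drug", "class", "any_antidepressant") or (
            kind != "any_antidepressant" and not rest
        ):
            raise ValueError(f"malformed exposure spec: {self.exposure!r}")


@dataclass(frozen=True)
class FitDiagnostics:
    converged: bool
    iterations: int
    log_likelihood: float
    n_used: int
    note: str = ""


def exposure_set(spec: str, catalog: DrugCatalog) -> frozenset[str]:
    """Resolve an exposure spec to the casefolded set of exposing codes."""
    kind, _, rest = spec.partition(":")
    if kind == "drug":
        code = rest.strip().casefold()
        if code not in catalog.antidepressants:
            raise KeyError(f"drug {rest!r} not in the catalog")
        return frozenset({code})
    if kind == "class":
        name = rest.strip().upper()
        if name not in CLASSES:
            raise KeyError(f"unknown class {rest!r}")
        return catalog.members(name)
    if kind == "any_antidepressant":
        return catalog.antidepressants
    raise ValueError(f"malformed exposure spec: {spec!r}")


def _design_matrix(
    dataset: Dataset,
    design: AnalysisDesign,
    dictionary: TermDictionary,
    catalog: DrugCatalog,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(y, X, exposure_column) for the logistic fit.  X starts with the
    intercept, then the exposure indicator, then covariates in a canonical
    internal order (the exposure estimate is invariant to the order the
    caller listed covariates in)."""
    n = len(dataset)
    y = case_flags(dataset, design.outcome_subtype, dictionary).astype(float)
    expo_codes = exposure_set(design.exposure, catalog)
    exposed = np.fromiter(
        (bool(r.drugs_casefolded() & expo_codes) for r in dataset),
        dtype=float,
        count=n,
    )
    cols: list[np.ndarray] = [np.ones(n), exposed]
    wanted = set(design.covariates)
    if "age" in wanted:
        age = np.fromiter(
            (math.nan if r.age is None else r.age for r in dataset),
            dtype=float,
            count=n,
        )
        if np.isnan(age).any():
            raise ValueError(
                "missing age in an adjusted fit; apply exclusions first"
            )
        if design.age_coding == "continuous":
            cols.append(age)
        else:
            # indicator per band above the reference (youngest) band
            for lo in AGE_BAND_EDGES:
                cols.append((age >= lo).astype(float))
    if "sex" in wanted:
        sexes = [r.sex for r in dataset]
        if "unknown" in sexes:
            raise ValueError(
                "unknown sex in an adjusted fit; apply exclusions first"
            )
        cols.append(np.array([1.0 if s == "male" else 0.0 for s in sexes]))
    if "inducer" in wanted or "treater" in wanted:
        drugsets = [r.drugs_casefolded() for r in dataset]
        if "inducer" in wanted:
            cols.append(
                np.array([1.0 if ds & catalog.inducers else 0.0 for ds in drugsets])
            )
        if "treater" in wanted:
            cols.append(
                np.array([1.0 if ds & catalog.treaters else 0.0 for ds in drugsets])
            )
    return y, np.column_stack(cols), exposed.astype(bool)


def fit_adjusted_ror(
    dataset: Dataset,
    design: AnalysisDesign,
    dictionary: TermDictionary,
    catalog: DrugCatalog,
) -> tuple[RorResult, FitDiagnostics]:
    """Fit the adjusted logistic model and return the exposure aROR.

    The estimate is the exponentiated exposure coefficient; the CI comes
    from the coefficient's standard error at ``design.confidence`` and the
    p-value from the two-sided Wald test, matching the CI construction.
    Significance follows the screening rule (aROR > 1, p < alpha, >=
    ``min_cases`` exposed cases).

    A comparison whose 2x2 margin has an empty cell is undefined (estimate
    withheld) without attempting a fit; non-convergence or perfect
    separation likewise yields an undefined result, flagged in the
    diagnostics note.
    """
    y, X, exposed = _design_matrix(dataset, design, dictionary, catalog)
    n = len(dataset)
    table = build_table_from_flags(exposed, y.astype(bool))
    undefined = RorResult(
        estimate=None,
        ci_low=None,
        ci_high=None,
        p_value=float("nan"),
        n_exposed_cases=table.a,
        method="adjusted",
        significant=False,
    )
    if min(table.a, table.b, table.c, table.d) == 0:
        return undefined, FitDiagnostics(
            converged=False,
            iterations=0,
            log_likelihood=float("nan"),
            n_used=n,
            note="empty contingency cell",
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return undefined, FitDiagnostics(
            converged=False,
            iterations=0,
            log_likelihood=float("nan"),
            n_used=n,
            note="perfect separation or singular design",
        )
    diag = FitDiagnostics(
        converged=bool(fit.mle_retvals.get("converged", False)),
        iterations=int(fit.mle_retvals.get("iterations", 0)),
        log_likelihood=float(fit.llf),
        n_used=n,
    )
    if not diag.converged:
        return undefined, FitDiagnostics(
            converged=False,
            iterations=diag.iterations,
            log_likelihood=diag.log_likelihood,
            n_used=n,
            note="maximum-likelihood iteration did not converge",
        )
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    from scipy.stats import norm

    z = float(norm.ppf(0.5 + design.confidence / 2))
    p = float(2 * norm.sf(abs(beta) / se)) if se > 0 else 0.0
    result = RorResult(
        estimate=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        p_value=p,
        n_exposed_cases=table.a,
        method="adjusted",
    )
    return flag_significance(result, design.alpha, design.min_cases), diag


def _result_row(exposure: str, subtype: str, res: RorResult, diag: FitDiagnostics) -> dict:
    return {
        "exposure": exposure,
        "subtype": subtype,
        "estimate": res.estimate,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "p_value": res.p_value,
        "n_exposed_cases": res.n_exposed_cases,
        "significant": res.significant,
        "method": res.method,
        "converged": diag.converged,
    }


def class_comparison(
    dataset: Dataset,
    dictionary: TermDictionary,
    catalog: DrugCatalog,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.001,
    min_cases: int = 10,
    confidence: float = 0.95,
    age_coding: str = "continuous",
) -> pd.DataFrame:
    """aROR of each antidepressant class against the other three, for every
    subtype.  Long-format DataFrame with ``len(CLASSES) x n_subtypes``
    rows; a class absent from the dataset yields undefined rows."""
    rows = []
    for class_name in CLASSES:
        for subtype in dictionary.names():
            design = AnalysisDesign(
                outcome_subtype=subtype,
                exposure=f"class:{class_name}",
                covariates=covariates,
                alpha=alpha,
                min_cases=min_cases,
                confidence=confidence,
                age_coding=age_coding,
            )
            res, diag = fit_adjusted_ror(dataset, design, dictionary, catalog)
            rows.append(_result_row(class_name, subtype, res, diag))
    return pd.DataFrame(rows)


def drug_comparison(
    dataset: Dataset,
    dictionary: TermDictionary,
    catalog: DrugCatalog,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.001,
    min_cases: int = 10,
    confidence: float = 0.95,
    age_coding: str = "continuous",
) -> pd.DataFrame:
    """aROR of each single antidepressant against all other reports in the
    analyzed dataset, for every subtype.  Rows follow the catalog's drug
    ordering; drugs absent from the dataset yield undefined rows."""
    rows = []
    for drug in catalog.order:
        for subtype in dictionary.names():
            design = AnalysisDesign(
                outcome_subtype=subtype,
                exposure=f"drug:{drug}",
                covariates=covariates,
                alpha=alpha,
                min_cases=min_cases,
                confidence=confidence,
                age_coding=age_coding,
            )
            res, diag = fit_adjusted_ror(dataset, design, dictionary, catalog)
            rows.append(_result_row(drug, subtype, res, diag))
    return pd.DataFrame(rows)


def sensitivity_restricted_period(
    dataset: Dataset,
    drug: str,
    design: AnalysisDesign,
    dictionary: TermDictionary,
    catalog: DrugCatalog,
) -> tuple[RorResult, tuple[int, int] | None]:
    """Refit restricting the study period to years since the drug's first
    report.

    The window starts at the catalog's configured ``first_year`` for the
    drug or, when unconfigured, at the earliest report year mentioning the
    drug in ``dataset``; it ends at the dataset's last report year.
    Returns the refit result and the ``(start, end)`` window (``None`` with
    an undefined result when the restriction empties the dataset or the
    drug never appears)."""
    code = drug.strip().casefold()
    first = catalog.first_year.get(code)
    if first is None:
        years = [r.year for r in dataset if code in r.drugs_casefolded()]
        if not years:
            undef = RorResult(
                estimate=None,
                ci_low=None,
                ci_high=None,
                p_value=float("nan"),
                n_exposed_cases=0,
                method="adjusted",
                significant=False,
            )
            return undef, None
        first = min(years)
    kept = [r for r in dataset if r.year >= first]
    if not kept:
        undef = RorResult(
            estimate=None,
            ci_low=None,
            ci_high=None,
            p_value=float("nan"),
            n_exposed_cases=0,
            method="adjusted",
            significant=False,
        )
        return undef, None
    restricted = Dataset(reports=kept, provenance=dataset.provenance)
    res, _ = fit_adjusted_ror(restricted, design, dictionary, catalog)
    last = max(r.year for r in kept)
    return res, (first, last)


def results_to_wide(results: pd.DataFrame, star_significant: bool = True) -> pd.DataFrame:
    """Pivot a long-format comparison table to the exposures-by-subtypes
    presentation shape: ``estimate [ci_low-ci_high]`` strings, starred when
    significant, em-dash for undefined entries."""

    def fmt(row) -> str:
        if row["estimate"] is None or (
            isinstance(row["estimate"], float) and math.isnan(row["estimate"])
        ):
            return "-"
        s = f"{row['estimate']:.2f} [{row['ci_low']:.2f}-{row['ci_high']:.2f}]"
        if star_significant and row["significant"]:
            s += "*"
        return s

    shaped = results.assign(cell=results.apply(fmt, axis=1))
    wide = shaped.pivot(index="exposure", columns="subtype", values="cell")
    return wide.reindex(index=results["exposure"].unique())
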