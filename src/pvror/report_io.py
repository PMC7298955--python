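"""Report data model and plain-text I/O for spontaneous-report datasets.

An individual case safety report (ICSR) is one spontaneous notification of a
suspected adverse drug reaction: patient demographics, the drugs on the
report, and the reaction terms coded at MedDRA Preferred-Term (PT) level.
This module defines the in-memory :class:`Report`/:class:`Dataset` model, a
canonical delimited text layout (CSV with semicolon-joined multi-valued
cells), a record-per-line JSON dialect, and a demographic summary.

Missing-data conventions
------------------------
Files encode a missing value as an empty cell.  In memory, age, country and
notifier use ``None`` as the missing sentinel; sex and seriousness carry a
real ``"unknown"`` level (spontaneous-report systems genuinely record
"unknown", it is not the same thing as an unparseable cell, but an empty
cell is recoded to it because the two cannot be told apart in a flat file).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Report",
    "Dataset",
    "DatasetValidationError",
    "RowError",
    "read_reports",
    "write_reports",
    "summarize_dataset",
    "REPORT_COLUMNS",
    "SEX_LEVELS",
    "SERIOUS_LEVELS",
    "LIST_DELIMITER",
    "AGE_BANDS",
]

SEX_LEVELS = ("female", "male", "unknown")
SERIOUS_LEVELS = ("yes", "no", "unknown")

#: Column order of the canonical delimited layout.
REPORT_COLUMNS = (
    "report_id",
    "year",
    "age",
    "sex",
    "country",
    "serious",
    "notifier",
    "drugs",
    "reactions",
)

#: Intra-cell delimiter for multi-valued cells (drugs, reactions).  Semicolon,
#: because the record delimiter is the comma.
LIST_DELIMITER = ";"

# Recoding tables applied on read (after casefolding and trimming).  These
# absorb the common dialects of source extracts; anything not listed is a
# row-level error, never silently passed through.
_SEX_RECODING = {
    "female": "female",
    "f": "female",
    "2": "female",
    "male": "male",
    "m": "male",
    "1": "male",
    "unknown": "unknown",
    "u": "unknown",
    "": "unknown",
}
_SERIOUS_RECODING = {
    "yes": "yes",
    "y": "yes",
    "1": "yes",
    "true": "yes",
    "no": "no",
    "n": "no",
    "0": "no",
    "false": "no",
    "unknown": "unknown",
    "u": "unknown",
    "": "unknown",
}

#: Age bands used for demographic summaries (years, lower bound inclusive).
AGE_BANDS = ((0, 5), (5, 18), (18, 45), (45, 65), (65, 75), (75, math.inf))


class DatasetValidationError(ValueError):
    """Raised when a dataset or input file violates the report contract.

    Carries the list of :class:`RowError` collected while parsing so that a
    caller sees every bad row at once, not just the first.
    """

    def __init__(self, message: str, row_errors: Sequence["RowError"] = ()):
        super().__init__(message)
        self.row_errors = list(row_errors)


@dataclass(frozen=True)
class RowError:
    """One malformed input row: line number, offending field, message."""

    line: int
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}, field '{self.field}': {self.message}"


@dataclass(frozen=True)
class Report:
    """One spontaneous adverse-event report.

    ``drugs`` and ``reactions`` are frozensets of the verbatim strings from
    the source; all matching elsewhere in the package is case-insensitive
    after whitespace trimming, so original casing is preserved through a
    read/write round-trip.
    """

    report_id: str
    year: int
    age: float | None
    sex: str
    country: str | None
    serious: str
    notifier: str | None
    drugs: frozenset[str]
    reactions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if self.age is not None and not (math.isfinite(self.age) and self.age >= 0):
            raise ValueError(f"age must be finite and >= 0, got {self.age!r}")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"sex must be one of {SEX_LEVELS}, got {self.sex!r}")
        if self.serious not in SERIOUS_LEVELS:
            raise ValueError(
                f"serious must be one of {SERIOUS_LEVELS}, got {self.serious!r}"
            )
        if not self.drugs:
            raise ValueError("drugs must contain at least one code")
        if not self.reactions:
            raise ValueError("reactions must contain at least one term")

    # The casefolded views are memoized in __dict__ (allowed on a frozen
    # dataclass) because every analysis pass over a large dataset needs them.
    def drugs_casefolded(self) -> frozenset[str]:
        cf = self.__dict__.get("_drugs_cf")
        if cf is None:
            cf = frozenset(d.strip().casefold() for d in self.drugs)
            self.__dict__["_drugs_cf"] = cf
        return cf

    def reactions_casefolded(self) -> frozenset[str]:
        cf = self.__dict__.get("_reactions_cf")
        if cf is None:
            cf = frozenset(r.strip().casefold() for r in self.reactions)
            self.__dict__["_reactions_cf"] = cf
        return cf


@dataclass
class Dataset:
    """Ordered collection of reports with a free-text provenance label."""

    reports: list[Report]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.reports]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dupes = sorted({i for i in ids if i in seen or seen.add(i)})
            raise DatasetValidationError(
                f"duplicate report_id(s): {', '.join(dupes[:10])}"
            )

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self.reports)

    def to_frame(self) -> pd.DataFrame:
        """Columnar view; ``drugs``/``reactions`` columns hold frozensets."""
        return pd.DataFrame(
            {
                "report_id": [r.report_id for r in self.reports],
                "year": [r.year for r in self.reports],
                "age": [np.nan if r.age is None else r.age for r in self.reports],
                "sex": [r.sex for r in self.reports],
                "serious": [r.serious for r in self.reports],
                "drugs": [r.drugs for r in self.reports],
                "reactions": [r.reactions for r in self.reports],
            }
        )


def _parse_list_cell(cell: str) -> frozenset[str]:
    return frozenset(
        part.strip() for part in cell.split(LIST_DELIMITER) if part.strip()
    )


def _format_list_cell(values: frozenset[str]) -> str:
    return LIST_DELIMITER.join(sorted(values))


def _parse_row(
    row: Mapping[str, str], line: int, errors: list[RowError]
) -> Report | None:
    """Parse one delimited row into a Report, collecting errors."""
    ok = True

    def err(fieldname: str, message: str) -> None:
        nonlocal ok
        ok = False
        errors.append(RowError(line, fieldname, message))

    report_id = (row.get("report_id") or "").strip()
    if not report_id:
        err("report_id", "empty report identifier")

    year_cell = (row.get("year") or "").strip()
    year = 0
    try:
        year = int(year_cell)
    except ValueError:
        # report year is required: the restricted-period sensitivity analysis
        # cannot run on undated reports.
        err("year", f"missing or non-integer report year: {year_cell!r}")

    age_cell = (row.get("age") or "").strip()
    age: float | None = None
    if age_cell:
        try:
            age = float(age_cell)
        except ValueError:
            err("age", f"non-numeric age: {age_cell!r}")
        else:
            if not (math.isfinite(age) and age >= 0):
                err("age", f"age out of domain: {age!r}")

    sex_cell = (row.get("sex") or "").strip().casefold()
    sex = _SEX_RECODING.get(sex_cell)
    if sex is None:
        err("sex", f"unrecognized sex code: {sex_cell!r}")

    serious_cell = (row.get("serious") or "").strip().casefold()
    serious = _SERIOUS_RECODING.get(serious_cell)
    if serious is None:
        err("serious", f"unrecognized seriousness code: {serious_cell!r}")

    country = (row.get("country") or "").strip() or None
    notifier = (row.get("notifier") or "").strip() or None

    drugs = _parse_list_cell(row.get("drugs") or "")
    if not drugs:
        err("drugs", "empty drug list")
    reactions = _parse_list_cell(row.get("reactions") or "")
    if not reactions:
        err("reactions", "empty reaction list")

    if not ok:
        return None
    return Report(
        report_id=report_id,
        year=year,
        age=age,
        sex=sex,  # type: ignore[arg-type]
        country=country,
        serious=serious,  # type: ignore[arg-type]
        notifier=notifier,
        drugs=drugs,
        reactions=reactions,
    )


def read_reports(path: str | Path, dialect: str = "delimited") -> Dataset:
    """Read a report dataset from ``path``.

    Parameters
    ----------
    path
        Input file location.
    dialect
        ``"delimited"`` for the canonical CSV layout (header required,
        semicolon-joined multi-valued cells) or ``"record-per-line"`` for
        one JSON object per line with the same field names (drugs and
        reactions as JSON arrays).

    Raises
    ------
    DatasetValidationError
        If the header is incomplete, any row is malformed (every bad row is
        reported with its line number and field), or a report_id repeats.
    """
    path = Path(path)
    errors: list[RowError] = []
    reports: list[Report] = []

    if dialect == "delimited":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise DatasetValidationError(f"{path}: empty file, header required")
            missing = set(REPORT_COLUMNS) - set(reader.fieldnames)
            if missing:
                raise DatasetValidationError(
                    f"{path}: header missing column(s): {', '.join(sorted(missing))}"
                )
            for line, row in enumerate(reader, start=2):
                report = _parse_row(row, line, errors)
                if report is not None:
                    reports.append(report)
    elif dialect == "record-per-line":
        with path.open(encoding="utf-8") as fh:
            for line, raw in enumerate(fh, start=1):
                raw = raw.strip()
                if not raw:
                    continue
                try:
                    obj = json.loads(raw)
                except json.JSONDecodeError as exc:
                    errors.append(RowError(line, "<record>", f"invalid JSON: {exc}"))
                    continue
                row = {
                    k: (
                        LIST_DELIMITER.join(v)
                        if isinstance(v, list)
                        else ("" if v is None else str(v))
                    )
                    for k, v in obj.items()
                }
                report = _parse_row(row, line, errors)
                if report is not None:
                    reports.append(report)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    if errors:
        raise DatasetValidationError(
            f"{path}: {len(errors)} malformed row(s); first: {errors[0]}", errors
        )
    return Dataset(reports=reports, provenance=str(path))


def write_reports(
    dataset: Dataset, path: str | Path, dialect: str = "delimited"
) -> Path:
    """Write ``dataset`` to ``path`` in the canonical layout.

    ``read_reports(write_reports(ds, p), dialect)`` reproduces ``ds`` field
    by field (multi-valued cells are written sorted; sets compare equal).
    """
    path = Path(path)
    if dialect == "delimited":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(REPORT_COLUMNS)
            for r in dataset:
                writer.writerow(
                    [
                        r.report_id,
                        str(r.year),
                        "" if r.age is None else repr(float(r.age)),
                        r.sex,
                        r.country or "",
                        r.serious,
                        r.notifier or "",
                        _format_list_cell(r.drugs),
                        _format_list_cell(r.reactions),
                    ]
                )
    elif dialect == "record-per-line":
        with path.open("w", encoding="utf-8") as fh:
            for r in dataset:
                fh.write(
                    json.dumps(
                        {
                            "report_id": r.report_id,
                            "year": r.year,
                            "age": r.age,
                            "sex": r.sex,
                            "country": r.country,
                            "serious": r.serious,
                            "notifier": r.notifier,
                            "drugs": sorted(r.drugs),
                            "reactions": sorted(r.reactions),
                        }
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    return path


def _breakdown(labels: Iterable[str], order: Sequence[str]) -> pd.DataFrame:
    counts = pd.Series(list(labels), dtype="object").value_counts()
    counts = counts.reindex(order, fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "count": counts.astype(int),
            "proportion": counts / total if total else np.nan,
        }
    )


def _age_band_label(age: float | None) -> str:
    if age is None:
        return "unknown"
    for lo, hi in AGE_BANDS:
        if lo <= age < hi:
            return f"{lo}+" if math.isinf(hi) else f"{lo}-{hi - 1}"
    return "unknown"  # pragma: no cover - bands span [0, inf)


def summarize_dataset(dataset: Dataset) -> dict:
    """Demographic summary: sex / age-band / seriousness breakdowns,
    female-to-male ratio among known-sex reports, and age moments among
    reports with a recorded age.

    The ratio is ``NaN`` (undefined) when the male count is zero; each
    breakdown includes its unknown category and its proportions sum to 1.
    """
    sexes = [r.sex for r in dataset]
    ages = np.array([r.age for r in dataset if r.age is not None], dtype=float)
    band_order = [
        f"{lo}+" if math.isinf(hi) else f"{lo}-{hi - 1}" for lo, hi in AGE_BANDS
    ] + ["unknown"]
    n_female = sexes.count("female")
    n_male = sexes.count("male")
    return {
        "n": len(dataset),
        "sex": _breakdown(sexes, list(SEX_LEVELS)),
        "age_band": _breakdown((_age_band_label(r.age) for r in dataset), band_order),
        "serious": _breakdown((r.serious for r in dataset), list(SERIOUS_LEVELS)),
        "sex_ratio": (n_female / n_male) if n_male else float("nan"),
        "age_mean": float(ages.mean()) if ages.size else float("nan"),
        "age_sd": float(ages.std(ddof=1)) if ages.size > 1 else float("nan"),
    }
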