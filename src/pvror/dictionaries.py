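"""Movement-disorder term dictionary and antidepressant drug catalog.

Two reference objects drive every analysis in the package:

* :class:`TermDictionary` — maps each of nine movement-disorder subtypes
  (akathisia, bruxism, dystonia, myoclonus, parkinsonism, restless legs
  syndrome, tardive dyskinesia, tics, tremor) to the set of MedDRA
  Preferred Terms that identify it on a report.  The default dictionary is
  adapted from the Standardised MedDRA Queries for movement disorders.
* :class:`DrugCatalog` — the 58 antidepressants under study partitioned
  into four ATC-convention classes (tricyclics, serotonin reuptake
  inhibitors, monoamine-oxidase inhibitors, "other"), plus two co-medication
  lists used as confounders: drugs able to induce movement disorders and
  drugs used to treat them, and an optional first-report year per drug for
  the restricted-period sensitivity analysis.

Both are overridable from a YAML configuration; defaults ship in code so the
pipeline runs with no external files.  The default inducer/treater lists are
deliberately small, documented placeholders (typical antipsychotics /
antiparkinsonian agents): real analyses should supply their own ATC-derived
lists via configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .report_io import Report

__all__ = [
    "SUBTYPES",
    "CLASSES",
    "TermDictionary",
    "DrugCatalog",
    "CatalogError",
    "default_term_dictionary",
    "default_drug_catalog",
    "load_catalog",
    "comedication_flags",
]

SUBTYPES = (
    "akathisia",
    "bruxism",
    "dystonia",
    "myoclonus",
    "parkinsonism",
    "restless_legs_syndrome",
    "tardive_dyskinesia",
    "tics",
    "tremor",
)

CLASSES = ("TCA", "SRI", "MAOI", "OTHER")

# Preferred Terms per subtype (30 PTs, pairwise disjoint).
_DEFAULT_TERMS: dict[str, tuple[str, ...]] = {
    "akathisia": ("Akathisia",),
    "bruxism": ("Bruxism",),
    "dystonia": (
        "Dystonia",
        "Dystonic tremor",
        "Oculogyric crisis",
        "Opisthotonus",
        "Oromandibular dystonia",
        "Pleurothotonus",
        "Torticollis",
        "Trismus",
    ),
    "myoclonus": ("Eyelid myoclonus", "Myoclonus"),
    "parkinsonism": (
        "Akinesia",
        "Bradykinesia",
        "Hypokinesia",
        "Parkinson's disease",
        "Parkinsonian crisis",
        "Parkinsonian gait",
        "Parkinsonian rest tremor",
        "Parkinsonism",
        "Reduced facial expression",
    ),
    "restless_legs_syndrome": ("Restless legs syndrome",),
    "tardive_dyskinesia": ("Tardive dyskinesia",),
    "tics": ("Tic",),
    "tremor": (
        "Action tremor",
        "Essential tremor",
        "Intention tremor",
        "Postural tremor",
        "Resting tremor",
        "Tremor",
    ),
}

# The 58 antidepressants, classed per ATC convention: N06AA -> TCA,
# N06AB -> SRI, N06AF/N06AG -> MAOI, everything else -> OTHER.
_DEFAULT_CLASSES: dict[str, tuple[str, ...]] = {
    # 19 tricyclic (and closely related non-selective reuptake) agents
    "TCA": (
        "amineptine",
        "amitriptyline",
        "amoxapine",
        "butriptyline",
        "clomipramine",
        "desipramine",
        "dibenzepin",
        "dosulepin",
        "doxepin",
        "imipramine",
        "iprindole",
        "lofepramine",
        "maprotiline",
        "melitracen",
        "nortriptyline",
        "opipramol",
        "protriptyline",
        "quinupramine",
        "trimipramine",
    ),
    # 8 serotonin reuptake inhibitors
    "SRI": (
        "citalopram",
        "escitalopram",
        "etoperidone",
        "fluoxetine",
        "fluvoxamine",
        "paroxetine",
        "sertraline",
        "zimeldine",
    ),
    # 8 monoamine-oxidase inhibitors (non-selective and MAO-A)
    "MAOI": (
        "iproclozide",
        "iproniazide",
        "isocarboxazid",
        "moclobemide",
        "nialamide",
        "phenelzine",
        "toloxatone",
        "tranylcypromine",
    ),
    # 23 "other" antidepressants
    "OTHER": (
        "agomelatine",
        "bifemelane",
        "bupropion",
        "desvenlafaxine",
        "duloxetine",
        "hypericum perforatum",
        "medifoxamine",
        "mianserin",
        "milnacipran",
        "minaprine",
        "mirtazapine",
        "nefazodone",
        "nomifensine",
        "oxaflozane",
        "oxitriptan",
        "reboxetine",
        "tianeptine",
        "trazodone",
        "tryptophan",
        "venlafaxine",
        "vilazodone",
        "viloxazine",
        "vortioxetine",
    ),
}

# Placeholder confounder co-medication lists (configurable; see module
# docstring).  Typical dopamine-blocking inducers and antiparkinsonian /
# symptomatic treaters.
_DEFAULT_INDUCERS = (
    "haloperidol",
    "risperidone",
    "olanzapine",
    "quetiapine",
    "aripiprazole",
    "chlorpromazine",
    "metoclopramide",
    "lithium",
    "valproate",
    "flunarizine",
)
_DEFAULT_TREATERS = (
    "levodopa",
    "trihexyphenidyl",
    "biperiden",
    "pramipexole",
    "ropinirole",
    "rotigotine",
    "amantadine",
    "tetrabenazine",
    "clonazepam",
    "propranolol",
)


class CatalogError(ValueError):
    """Invalid term dictionary or drug catalog configuration."""


def _casefold_set(values: Sequence[str] | frozenset[str]) -> frozenset[str]:
    return frozenset(v.strip().casefold() for v in values)


@dataclass(frozen=True)
class TermDictionary:
    """Mapping subtype -> set of Preferred-Term strings.

    PT matching throughout the package is case-insensitive after whitespace
    trimming.  A PT may belong to at most one subtype unless
    ``allow_overlap`` is set (the default dictionary is disjoint).
    """

    subtypes: Mapping[str, frozenset[str]]
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if not self.subtypes:
            raise CatalogError("term dictionary has no subtypes")
        for name, terms in self.subtypes.items():
            if not terms:
                raise CatalogError(f"subtype {name!r} has an empty PT set")
        if not self.allow_overlap:
            seen: dict[str, str] = {}
            for name, terms in self.subtypes.items():
                for pt in _casefold_set(terms):
                    if pt in seen:
                        raise CatalogError(
                            f"PT {pt!r} appears in both {seen[pt]!r} and {name!r}"
                        )
                    seen[pt] = name

    def names(self) -> tuple[str, ...]:
        return tuple(self.subtypes)

    def terms(self, subtype: str) -> frozenset[str]:
        if subtype not in self.subtypes:
            raise KeyError(f"unknown subtype: {subtype!r}")
        return self.subtypes[subtype]

    def terms_casefolded(self, subtype: str) -> frozenset[str]:
        return _casefold_set(self.terms(subtype))

    def all_terms(self) -> frozenset[str]:
        out: set[str] = set()
        for terms in self.subtypes.values():
            out |= terms
        return frozenset(out)


def default_term_dictionary() -> TermDictionary:
    """The built-in nine-subtype movement-disorder PT dictionary (30 PTs)."""
    return TermDictionary(
        subtypes={name: frozenset(terms) for name, terms in _DEFAULT_TERMS.items()}
    )


@dataclass(frozen=True)
class DrugCatalog:
    """Antidepressant classes plus confounder co-medication lists.

    All codes are stored casefolded; lookups are case-insensitive.  Class
    sets are pairwise disjoint and the inducer/treater lists are disjoint
    from the antidepressants (they are confounders *for* antidepressant
    exposure, so overlap would make the adjusted model incoherent).
    """

    class_of: Mapping[str, str]  # code -> class name
    inducers: frozenset[str]
    treaters: frozenset[str]
    first_year: Mapping[str, int] = field(default_factory=dict)
    #: catalog ordering of antidepressant codes (drives output row order)
    order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = sorted(set(self.class_of.values()) - set(CLASSES))
        if bad:
            raise CatalogError(f"unknown class name(s): {bad}")
        ads = frozenset(self.class_of)
        for label, codes in (("inducers", self.inducers), ("treaters", self.treaters)):
            overlap = sorted(codes & ads)
            if overlap:
                raise CatalogError(
                    f"{label} overlap the antidepressant list: {overlap}"
                )
        if not self.order:
            object.__setattr__(self, "order", tuple(sorted(self.class_of)))

    @property
    def antidepressants(self) -> frozenset[str]:
        return frozenset(self.class_of)

    def members(self, class_name: str) -> frozenset[str]:
        if class_name not in CLASSES:
            raise KeyError(f"unknown class: {class_name!r}")
        return frozenset(c for c, k in self.class_of.items() if k == class_name)

    def class_counts(self) -> dict[str, int]:
        counts = {k: 0 for k in CLASSES}
        for k in self.class_of.values():
            counts[k] += 1
        return counts

    def to_config(self) -> dict:
        """Serializable configuration equivalent of this catalog."""
        return {
            "classes": {k.lower(): sorted(self.members(k)) for k in CLASSES},
            "comedications": {
                "inducers": sorted(self.inducers),
                "treaters": sorted(self.treaters),
            },
            "first_year": dict(sorted(self.first_year.items())),
        }


def _build_catalog(
    classes: Mapping[str, Sequence[str]],
    inducers: Sequence[str],
    treaters: Sequence[str],
    first_year: Mapping[str, int] | None = None,
    expected_counts: Mapping[str, int] | None = None,
) -> DrugCatalog:
    class_of: dict[str, str] = {}
    order: list[str] = []
    for raw_name, codes in classes.items():
        name = raw_name.upper()
        if name not in CLASSES:
            raise CatalogError(f"unknown class name: {raw_name!r}")
        for code in codes:
            cc = code.strip().casefold()
            if not cc:
                raise CatalogError(f"empty drug code in class {name}")
            if cc in class_of:
                raise CatalogError(
                    f"drug {cc!r} assigned to both {class_of[cc]} and {name}"
                )
            class_of[cc] = name
            order.append(cc)
    if expected_counts:
        counts = {k: 0 for k in CLASSES}
        for k in class_of.values():
            counts[k] += 1
        for name, expected in expected_counts.items():
            if counts.get(name.upper()) != expected:
                raise CatalogError(
                    f"class {name.upper()} has {counts.get(name.upper())} drugs, "
                    f"expected {expected}"
                )
    fy = {
        k.strip().casefold(): int(v) for k, v in (first_year or {}).items()
    }
    return DrugCatalog(
        class_of=class_of,
        inducers=_casefold_set(inducers),
        treaters=_casefold_set(treaters),
        first_year=fy,
        order=tuple(order),
    )


def default_drug_catalog() -> DrugCatalog:
    """Built-in catalog: 58 antidepressants (19 TCA / 8 SRI / 8 MAOI /
    23 OTHER) with the placeholder inducer/treater lists."""
    return _build_catalog(
        _DEFAULT_CLASSES,
        _DEFAULT_INDUCERS,
        _DEFAULT_TREATERS,
        expected_counts={"TCA": 19, "SRI": 8, "MAOI": 8, "OTHER": 23},
    )


def load_catalog(config: Mapping | str | Path, strict: bool = False) -> DrugCatalog:
    """Build a :class:`DrugCatalog` from a config mapping or a YAML file.

    Expected keys: ``classes.{tca,sri,maoi,other}`` (code lists),
    ``comedications.{inducers,treaters}``, optional ``first_year`` mapping
    and optional ``expected_counts`` per class.  With ``strict`` set, the
    declared ``expected_counts`` must match the parsed class sizes.
    """
    if isinstance(config, (str, Path)):
        with Path(config).open(encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping) or "classes" not in config:
        raise CatalogError("catalog config must be a mapping with a 'classes' key")
    comeds = config.get("comedications", {}) or {}
    return _build_catalog(
        config["classes"],
        comeds.get("inducers", ()) or (),
        comeds.get("treaters", ()) or (),
        config.get("first_year"),
        expected_counts=config.get("expected_counts") if strict else None,
    )


def load_term_dictionary(config: Mapping | str | Path) -> TermDictionary:
    """Build a :class:`TermDictionary` from a ``{subtype: [PTs]}`` mapping
    or a YAML file with a top-level ``terms`` key (or the mapping itself)."""
    if isinstance(config, (str, Path)):
        with Path(config).open(encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    terms = config.get("terms", config) if isinstance(config, Mapping) else None
    if not isinstance(terms, Mapping):
        raise CatalogError("term config must map subtype -> list of PTs")
    return TermDictionary(
        subtypes={str(k): frozenset(map(str, v)) for k, v in terms.items()}
    )


def comedication_flags(report: Report, catalog: DrugCatalog) -> tuple[bool, bool]:
    """(inducer_flag, treater_flag): whether the report's drug set intersects
    the catalog's movement-disorder-inducing / -treating lists."""
    drugs = report.drugs_casefolded()
    return bool(drugs & catalog.inducers), bool(drugs & catalog.treaters)
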