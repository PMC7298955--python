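"""Synthetic spontaneous-report generator.

Spontaneous-report databases cannot generally be redistributed, so every
pipeline stage here is exercised on generated data with the same
statistical structure: configurable per-drug exposure prevalences, planted
drug–event log-odds associations, covariate effects (age, sex, co-reported
movement-disorder-inducing / -treating drugs) with optional
exposure-dependent co-medication rates to create genuine confounding,
female-skewed demographics, realistic missingness, and background noise
reactions so that no report has an empty reaction list.

Sampling model, per report: report year uniform over the configured span;
latent sex (female with the configured known-sex fraction) and latent age
(truncated normal) drive the outcome model and are masked to
unknown/missing afterwards; drug exposures are drawn either independently
per drug (database-wide shape) or as exactly one antidepressant per report
(the extraction shape used by the adjusted analyses); each movement-
disorder subtype's case status is an independent Bernoulli draw from a
logistic model ``baseline + planted effects + covariate effects``, and a
case contributes one Preferred Term sampled from that subtype's dictionary
list.

Randomness contract: a single mandatory integer seed; every variable draws
from its own named substream (spawned from the seed in a fixed order), so
generation is bit-reproducible and growing ``n_reports`` extends a dataset
without reshuffling earlier reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .adjusted_model import DEFAULT_COVARIATES, AnalysisDesign, fit_adjusted_ror
from .case_noncase import ExclusionCriteria, apply_exclusions
from .dictionaries import (
    DrugCatalog,
    TermDictionary,
    default_drug_catalog,
    default_term_dictionary,
)
from .disproportionality import crude_ror
from .case_noncase import build_table_from_flags, case_flags
from .report_io import Dataset, Report

__all__ = [
    "CovariateEffects",
    "GeneratorConfig",
    "generate",
    "paper_shaped_config",
    "null_config",
    "confounded_config",
    "recovery_harness",
]

# Fixed substream order; names are part of the reproducibility contract.
_STREAMS = (
    "year",
    "sex",
    "sex_missing",
    "age",
    "age_missing",
    "serious",
    "exposure",
    "comed_inducer",
    "comed_treater",
    "comed_pick",
    "comed_bg_count",
    "comed_bg_pick",
    "case",
    "pt_pick",
    "rxn_count",
    "rxn_pick",
)

#: Background (non-movement-disorder) reaction pool: common, unrelated PTs.
DEFAULT_BACKGROUND_REACTIONS = (
    "Nausea",
    "Headache",
    "Dizziness",
    "Rash",
    "Fatigue",
    "Vomiting",
    "Diarrhoea",
    "Insomnia",
    "Pruritus",
    "Somnolence",
    "Dry mouth",
    "Constipation",
    "Hyponatraemia",
    "Weight increased",
    "Anxiety",
    "Palpitations",
    "Sweating increased",
    "Sexual dysfunction",
    "Hepatitis",
    "Urticaria",
)

#: Neutral co-medication codes (neither inducers nor treaters).
DEFAULT_BACKGROUND_COMEDS = tuple(f"comed_{i:02d}" for i in range(1, 31))


@dataclass(frozen=True)
class CovariateEffects:
    """Log-odds contributions of the covariates to every subtype's outcome.

    ``age_per_decade`` applies to (age - 50)/10 so the baseline logits keep
    their interpretation at a typical reporting age; ``male`` is the shift
    for male versus female sex.
    """

    age_per_decade: float = 0.0
    male: float = 0.0
    inducer: float = 0.0
    treater: float = 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic dataset.

    ``planted_effects`` maps ``(exposure_spec, subtype)`` to a log-odds
    ratio, where the exposure spec uses the same grammar as the analysis
    designs (``"drug:<code>"``, ``"class:<NAME>"``, ``"any_antidepressant"``).
    ``drug_prevalence`` is per-drug Bernoulli probabilities in
    ``independent`` exposure mode, or categorical weights (one drug per
    report) in ``single`` mode.  ``inducer_prob_by_drug`` overrides the
    inducer co-medication probability for reports exposed to a given drug,
    which is how exposure-correlated confounding is planted.
    """

    n_reports: int
    seed: int
    catalog: DrugCatalog
    drug_prevalence: Mapping[str, float]
    baseline_logit: Mapping[str, float]
    planted_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    covariate_effects: CovariateEffects = CovariateEffects()
    dictionary: TermDictionary = field(default_factory=default_term_dictionary)
    exposure_mode: str = "independent"
    year_range: tuple[int, int] = (1995, 2016)
    female_fraction: float = 0.6826
    age_mean: float = 50.9
    age_sd: float = 18.0
    age_bounds: tuple[float, float] = (0.0, 110.0)
    missing_age_prob: float = 0.29
    missing_sex_prob: float = 0.05
    serious_probs: tuple[float, float, float] = (0.375, 0.293, 0.332)  # yes/no/unknown
    inducer_prob: float = 0.04
    treater_prob: float = 0.02
    inducer_prob_by_drug: Mapping[str, float] = field(default_factory=dict)
    comed_rate: float = 1.2
    background_reactions: tuple[str, ...] = DEFAULT_BACKGROUND_REACTIONS
    background_reaction_rate: float = 0.8
    background_comeds: tuple[str, ...] = DEFAULT_BACKGROUND_COMEDS
    provenance: str = "pvror synthetic"

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        if self.exposure_mode not in ("independent", "single"):
            raise ValueError("exposure_mode must be 'independent' or 'single'")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range start must be <= end")
        probs = [
            self.female_fraction,
            self.missing_age_prob,
            self.missing_sex_prob,
            self.inducer_prob,
            self.treater_prob,
            *self.drug_prevalence.values(),
            *self.inducer_prob_by_drug.values(),
            *self.serious_probs,
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.serious_probs) - 1) > 1e-9:
            raise ValueError("serious_probs must sum to 1")
        if not self.drug_prevalence:
            raise ValueError("drug_prevalence must name at least one drug")
        if not self.baseline_logit:
            raise ValueError("baseline_logit must cover at least one subtype")
        for s in self.baseline_logit:
            self.dictionary.terms(s)  # raises on unknown subtype
        for (spec, s) in self.planted_effects:
            if s not in self.baseline_logit:
                raise ValueError(f"planted effect on unsimulated subtype {s!r}")
            _planted_exposure_set(spec, self.catalog, self.drug_prevalence)
        if not self.background_reactions:
            raise ValueError("background_reactions pool must be non-empty")
        if not (self.age_bounds[0] < self.age_bounds[1]):
            raise ValueError("age_bounds must be an increasing pair")


def _planted_exposure_set(
    spec: str, catalog: DrugCatalog, prevalence: Mapping[str, float]
) -> frozenset[str]:
    """Exposure spec -> casefolded code set; unlike the analysis resolver,
    a planted drug need only appear in the prevalence map, not the catalog."""
    kind, _, rest = spec.partition(":")
    if kind == "drug":
        code = rest.strip().casefold()
        if code not in {k.strip().casefold() for k in prevalence}:
            raise ValueError(f"planted drug {rest!r} has no prevalence entry")
        return frozenset({code})
    if kind == "class":
        return catalog.members(rest.strip().upper())
    if kind == "any_antidepressant":
        return catalog.antidepressants
    raise ValueError(f"malformed exposure spec: {spec!r}")


def generate(config: GeneratorConfig) -> Dataset:
    """Sample a :class:`Dataset` under ``config``; deterministic in the seed."""
    config.validate()
    n = config.n_reports
    ss = np.random.SeedSequence(config.seed)
    rngs = dict(zip(_STREAMS, map(np.random.default_rng, ss.spawn(len(_STREAMS)))))

    years = rngs["year"].integers(config.year_range[0], config.year_range[1] + 1, n)
    female = rngs["sex"].random(n) < config.female_fraction
    sex_unknown = rngs["sex_missing"].random(n) < config.missing_sex_prob
    lo, hi = config.age_bounds
    a_, b_ = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age_true = truncnorm.ppf(
        rngs["age"].random(n), a_, b_, loc=config.age_mean, scale=config.age_sd
    )
    age_missing = rngs["age_missing"].random(n) < config.missing_age_prob
    serious_u = rngs["serious"].random(n)
    s_yes, s_no, _ = config.serious_probs

    drug_codes = [k.strip().casefold() for k in config.drug_prevalence]
    prev = np.array(list(config.drug_prevalence.values()), dtype=float)
    if config.exposure_mode == "independent":
        exposure = rngs["exposure"].random((n, len(drug_codes))) < prev
    else:
        cum = np.cumsum(prev / prev.sum())
        idx = np.searchsorted(cum, rngs["exposure"].random(n), side="right")
        idx = np.minimum(idx, len(drug_codes) - 1)
        exposure = np.zeros((n, len(drug_codes)), dtype=bool)
        exposure[np.arange(n), idx] = True

    p_ind = np.full(n, config.inducer_prob)
    for code, p in config.inducer_prob_by_drug.items():
        cc = code.strip().casefold()
        if cc in drug_codes:
            j = drug_codes.index(cc)
            p_ind = np.where(exposure[:, j], p, p_ind)
    has_inducer = rngs["comed_inducer"].random(n) < p_ind
    has_treater = rngs["comed_treater"].random(n) < config.treater_prob
    inducer_pool = sorted(config.catalog.inducers) or ["inducer_01"]
    treater_pool = sorted(config.catalog.treaters) or ["treater_01"]
    comed_pick = rngs["comed_pick"].integers(0, 2**31, n)
    bg_comed_counts = rngs["comed_bg_count"].poisson(config.comed_rate, n)
    # every report must list at least one drug
    bare = ~exposure.any(axis=1) & ~has_inducer & ~has_treater & (bg_comed_counts == 0)
    bg_comed_counts = np.where(bare, 1, bg_comed_counts)
    bg_comed_idx = rngs["comed_bg_pick"].integers(
        0, len(config.background_comeds), int(bg_comed_counts.sum())
    )
    comed_offsets = np.concatenate(([0], np.cumsum(bg_comed_counts)))

    subtypes = list(config.baseline_logit)
    S = len(subtypes)
    logits = np.tile(
        np.array([config.baseline_logit[s] for s in subtypes], dtype=float), (n, 1)
    )
    for (spec, subtype), beta in config.planted_effects.items():
        codes = _planted_exposure_set(spec, config.catalog, config.drug_prevalence)
        cols = [k for k, c in enumerate(drug_codes) if c in codes]
        if cols:
            logits[:, subtypes.index(subtype)] += beta * exposure[:, cols].any(axis=1)
    ce = config.covariate_effects
    shift = (
        ce.age_per_decade * (age_true - 50.0) / 10.0
        + ce.male * (~female)
        + ce.inducer * has_inducer
        + ce.treater * has_treater
    )
    cases = rngs["case"].random((n, S)) < expit(logits + shift[:, None])
    pt_u = rngs["pt_pick"].random((n, S))
    pt_lists = [sorted(config.dictionary.terms(s)) for s in subtypes]

    bg_rxn_counts = 1 + rngs["rxn_count"].poisson(config.background_reaction_rate, n)
    bg_rxn_idx = rngs["rxn_pick"].integers(
        0, len(config.background_reactions), int(bg_rxn_counts.sum())
    )
    rxn_offsets = np.concatenate(([0], np.cumsum(bg_rxn_counts)))

    ad_lists: list[list[str]] = [[] for _ in range(n)]
    exp_r, exp_c = np.nonzero(exposure)
    for r, c in zip(exp_r.tolist(), exp_c.tolist()):
        ad_lists[r].append(drug_codes[c])

    # one sampled PT per (report, subtype) case
    case_rxns: list[list[str]] = [[] for _ in range(n)]
    case_r, case_c = np.nonzero(cases)
    case_u = pt_u[case_r, case_c].tolist()
    for r, c, u in zip(case_r.tolist(), case_c.tolist(), case_u):
        pts = pt_lists[c]
        case_rxns[r].append(pts[int(u * len(pts))])

    # scalar extraction from numpy arrays is the hot path; go through lists
    bg_comed_names = [config.background_comeds[j] for j in bg_comed_idx.tolist()]
    bg_rxn_names = [config.background_reactions[j] for j in bg_rxn_idx.tolist()]
    comed_off = comed_offsets.tolist()
    rxn_off = rxn_offsets.tolist()
    years_l = years.tolist()
    ages_l = np.where(age_missing, np.nan, np.round(age_true, 1)).tolist()
    sexes_l = np.where(
        sex_unknown, "unknown", np.where(female, "female", "male")
    ).tolist()
    serious_l = np.where(
        serious_u < s_yes, "yes", np.where(serious_u < s_yes + s_no, "no", "unknown")
    ).tolist()
    ind_l = has_inducer.tolist()
    tre_l = has_treater.tolist()
    pick_l = comed_pick.tolist()

    reports: list[Report] = []
    for i in range(n):
        drugs = ad_lists[i]
        if ind_l[i]:
            drugs.append(inducer_pool[pick_l[i] % len(inducer_pool)])
        if tre_l[i]:
            drugs.append(treater_pool[pick_l[i] % len(treater_pool)])
        drugs += bg_comed_names[comed_off[i] : comed_off[i + 1]]
        age = ages_l[i]
        reports.append(
            Report(
                report_id=f"R{i:08d}",
                year=years_l[i],
                age=None if age != age else age,  # NaN marks masked age
                sex=sexes_l[i],
                country=None,
                serious=serious_l[i],
                notifier=None,
                drugs=frozenset(drugs),
                reactions=frozenset(
                    bg_rxn_names[rxn_off[i] : rxn_off[i + 1]] + case_rxns[i]
                ),
            )
        )
    return Dataset(reports=reports, provenance=config.provenance)


# Background per-subtype reporting rates among unexposed reports and the
# whole-database exposure log-odds the shaped generator plants.  These mirror
# the published database-wide screen of antidepressants and movement
# disorders (rates on the order of 1e-4..1e-2; effects from ~1.5 to ~10 on
# the odds-ratio scale).
_SHAPED_BACKGROUND_RATE = {
    "akathisia": 5.557e-4,
    "bruxism": 1.169e-4,
    "dystonia": 2.4066e-3,
    "myoclonus": 3.954e-4,
    "parkinsonism": 1.6831e-3,
    "restless_legs_syndrome": 4.614e-4,
    "tardive_dyskinesia": 1.633e-3,
    "tics": 5.034e-4,
    "tremor": 9.092e-3,
}
_SHAPED_EFFECT_OR = {
    "akathisia": 3.79,
    "bruxism": 10.37,
    "dystonia": 2.07,
    "myoclonus": 4.79,
    "parkinsonism": 2.14,
    "restless_legs_syndrome": 5.14,
    "tardive_dyskinesia": 1.55,
    "tics": 1.49,
    "tremor": 3.06,
}


def paper_shaped_config(n_reports: int = 100_000, seed: int = 0) -> GeneratorConfig:
    """A database-wide-shaped configuration.

    Marginals target the demographic structure of a large worldwide
    spontaneous-report database: known-sex female fraction 0.6826
    (female/male ratio 2.15), age 50.9 ± 18.0 years, 29% missing age, 5%
    unknown sex, ~7.2% of reports exposed to one of the 58 catalog
    antidepressants, and an overall movement-disorder rate among exposed
    reports of ~2.8%.  Per-subtype baseline reporting odds are calibrated
    (deterministically, at construction) so the planted per-subtype
    exposure effects produce that 2.8% aggregate rate; the calibration
    accounts analytically for the small odds inflation contributed by the
    covariate effects.
    """
    catalog = default_drug_catalog()
    drugs = list(catalog.order)
    # equal per-drug prevalence p with P(>=1 exposure) = 0.072
    p = 1.0 - (1.0 - 0.072) ** (1.0 / len(drugs))
    ce = CovariateEffects(age_per_decade=0.05, male=-0.10, inducer=0.70, treater=0.30)
    female, p_ind, p_tre = 0.6826, 0.04, 0.02
    # mean multiplicative covariate contribution on the odds scale
    # (lognormal mean for the age term; mixture means for the indicators)
    m = (
        math.exp(0.05 * 0.09 + 0.5 * (0.05 * 1.8) ** 2)
        * (female + (1 - female) * math.exp(-0.10))
        * (1 - p_ind + p_ind * math.exp(0.70))
        * (1 - p_tre + p_tre * math.exp(0.30))
    )
    betas = {s: math.log(orr) for s, orr in _SHAPED_EFFECT_OR.items()}

    def exposed_rate(scale: float) -> float:
        prod = 1.0
        for s, bg in _SHAPED_BACKGROUND_RATE.items():
            prod *= 1.0 - expit(math.log(scale * m) + logit(bg) + betas[s])
        return 1.0 - prod

    scale = brentq(lambda s: exposed_rate(s) - 0.028, 1e-3, 5.0)
    baseline = {
        s: float(math.log(scale) + logit(bg))
        for s, bg in _SHAPED_BACKGROUND_RATE.items()
    }
    return GeneratorConfig(
        n_reports=n_reports,
        seed=seed,
        catalog=catalog,
        drug_prevalence={d: p for d in drugs},
        baseline_logit=baseline,
        planted_effects={("any_antidepressant", s): b for s, b in betas.items()},
        covariate_effects=ce,
        exposure_mode="independent",
        year_range=(1967, 2016),
        female_fraction=female,
        missing_age_prob=0.29,
        missing_sex_prob=0.05,
        inducer_prob=p_ind,
        treater_prob=p_tre,
        provenance="pvror synthetic (database-wide shape)",
    )


_SINGLE_DRUG_OF_INTEREST = "citalopram"


def _extraction_shaped(
    n_reports: int,
    seed: int,
    planted_log_or: float,
    confounded: bool,
    subtype: str = "tremor",
) -> GeneratorConfig:
    """Shared construction for the single-antidepressant (extraction-shaped)
    simulation conditions used by the recovery studies."""
    catalog = default_drug_catalog()
    drugs = list(catalog.order)
    focus = _SINGLE_DRUG_OF_INTEREST
    weights = {d: (0.30 if d == focus else 0.70 / (len(drugs) - 1)) for d in drugs}
    return GeneratorConfig(
        n_reports=n_reports,
        seed=seed,
        catalog=catalog,
        drug_prevalence=weights,
        baseline_logit={subtype: float(logit(0.05))},
        planted_effects={(f"drug:{focus}", subtype): planted_log_or},
        covariate_effects=CovariateEffects(
            age_per_decade=0.10, male=0.20, inducer=1.00, treater=0.30
        ),
        exposure_mode="single",
        year_range=(1995, 2016),
        missing_age_prob=0.29,
        missing_sex_prob=0.05,
        inducer_prob=0.05,
        inducer_prob_by_drug={focus: 0.35} if confounded else {},
        treater_prob=0.03,
        provenance="pvror synthetic (extraction shape)",
    )


def null_config(n_reports: int = 20_000, seed: int = 0) -> GeneratorConfig:
    """No planted exposure effect (log-OR 0): the drug-of-interest aROR has
    true value 1.  Used for CI coverage and type-I error studies."""
    return _extraction_shaped(n_reports, seed, planted_log_or=0.0, confounded=False)


def confounded_config(
    n_reports: int = 200_000, seed: int = 0, planted_log_or: float = 0.7
) -> GeneratorConfig:
    """Planted exposure log-OR with upward confounding: reports exposed to
    the drug of interest carry an inducer co-medication far more often
    (0.35 vs 0.05), and the inducer itself raises the outcome log-odds by
    1.0, so the crude ROR overshoots exp(planted_log_or) while the
    adjusted model recovers it."""
    return _extraction_shaped(n_reports, seed, planted_log_or, confounded=True)


def recovery_harness(
    config: GeneratorConfig,
    n_seeds: int,
    criteria: ExclusionCriteria | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.001,
    min_cases: int = 10,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Repeated generate -> exclude -> fit cycle for every planted effect.

    For each ``(exposure_spec, subtype)`` key of ``config.planted_effects``
    (a zero value is a legitimate null entry) and each of ``n_seeds``
    deterministic derived seeds, the harness generates a dataset, applies
    the exclusion criteria, fits the adjusted model, and also computes the
    crude ROR of the same 2x2 table.  Returns one row per planted effect:
    the true odds ratio, mean adjusted and crude estimates, the coverage
    rate of the adjusted CI over the true value, power at ``alpha`` (the
    significance-flag rate; under a null entry this is the type-I error),
    and the count of failed/undefined fits (counted, not fatal).
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2 for a Monte-Carlo summary")
    config.validate()
    if criteria is None:
        criteria = ExclusionCriteria()
    children = np.random.SeedSequence(config.seed).spawn(n_seeds)
    seeds = [int(c.generate_state(1, np.uint32)[0] & 0x7FFFFFFF) for c in children]
    records: dict[tuple[str, str], dict[str, list]] = {
        key: {"adjusted": [], "crude": [], "covered": [], "significant": [], "failed": 0}
        for key in config.planted_effects
    }
    for seed in seeds:
        dataset = generate(replace(config, seed=seed))
        analyzed, _ = apply_exclusions(dataset, criteria, config.catalog)
        for (spec, subtype), beta in config.planted_effects.items():
            truth = math.exp(beta)
            design = AnalysisDesign(
                outcome_subtype=subtype,
                exposure=spec,
                covariates=covariates,
                alpha=alpha,
                min_cases=min_cases,
                confidence=confidence,
            )
            res, diag = fit_adjusted_ror(
                analyzed, design, config.dictionary, config.catalog
            )
            rec = records[(spec, subtype)]
            if not res.defined:
                rec["failed"] += 1  # type: ignore[operator]
                continue
            rec["adjusted"].append(res.estimate)
            rec["covered"].append(res.ci_low <= truth <= res.ci_high)
            rec["significant"].append(res.significant)
            from .adjusted_model import exposure_set

            codes = exposure_set(spec, config.catalog)
            exposed = np.fromiter(
                (bool(r.drugs_casefolded() & codes) for r in analyzed),
                dtype=bool,
                count=len(analyzed),
            )
            cases = case_flags(analyzed, subtype, config.dictionary)
            cr = crude_ror(build_table_from_flags(exposed, cases), confidence)
            rec["crude"].append(cr.estimate if cr.defined else math.nan)
    rows = []
    for (spec, subtype), beta in config.planted_effects.items():
        rec = records[(spec, subtype)]
        n_ok = len(rec["adjusted"])
        rows.append(
            {
                "exposure": spec,
                "subtype": subtype,
                "true_or": math.exp(beta),
                "n_seeds": n_seeds,
                "n_ok": n_ok,
                "n_failed": rec["failed"],
                "mean_adjusted": float(np.mean(rec["adjusted"])) if n_ok else math.nan,
                "mean_crude": float(np.nanmean(rec["crude"])) if n_ok else math.nan,
                "coverage": float(np.mean(rec["covered"])) if n_ok else math.nan,
                "power": float(np.mean(rec["significant"])) if n_ok else math.nan,
            }
        )
    return pd.DataFrame(rows)
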