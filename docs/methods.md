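# Methods

## The case/non-case design

`pvror` screens a spontaneous-report database for drug–event associations
with the case/non-case (disproportionality) design.  For an outcome
subtype, "cases" are the reports whose reaction set intersects that
subtype's Preferred-Term list and "non-cases" are all remaining reports;
the exposure contrast (a drug, a drug class, or any study antidepressant)
is drawn within the report database, never against a population
denominator.  A report may be a case for several subtypes at once; each
subtype is analyzed marginally.

Two analysis tiers mirror how such screens are run in practice:

* **Crude whole-database screen** (`whole_database_screen`): each subtype's
  2×2 table contrasts reports with ≥1 catalog antidepressant against every
  other report in the full dataset.  No exclusion filtering is applied at
  this tier — it emulates a database-wide query, which has no covariate
  information requirements.
* **Adjusted comparisons** (`class_comparison`, `drug_comparison`,
  `fit_adjusted_ror`): run on the antidepressant extraction after
  exclusion filtering, with one logistic model per exposure (the literal
  "one comparison per drug" family that the Bonferroni correction counts),
  never a joint multi-drug model.

## Estimators

**Crude ROR.** `ad/bc` with the Wald interval on the log scale,
`exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))`, and a two-sided Wald p-value from
`ln(ROR)/SE`.  The Wald pair was chosen because it is the construction
that exactly reproduces published whole-database screen intervals of this
kind at the printed precision (verified in the test suite for all nine
subtypes), and because using the same machinery for CI and p-value keeps
the two consistent.  No continuity correction is applied: a table with an
empty cell yields an *undefined* result (estimate and CI withheld, flag
false), matching the convention of printing a dash rather than a
Haldane–Anscombe-corrected value.

**Adjusted ROR.** Maximum-likelihood logistic regression (statsmodels
Newton solver, convergence tolerance 1e-8, 100-iteration cap) of the case
indicator on the exposure indicator plus covariates; the aROR is the
exponentiated exposure coefficient with Wald CI and p-value from its
standard error.  The zero-covariate fit reproduces the crude ROR to 1e-6
relative (nested-model identity, tested).  Non-convergence and perfect
separation are reported as undefined results with a diagnostics note, not
as numbers.  A comparison whose 2×2 table already has an empty margin is
declared undefined without attempting a fit.

**Covariates.** Age enters continuously in years by default; an age-band
coding (18/45/65/75 cut-points) is available because the appropriate
coding for reporting data is genuinely open and band effects need not be
log-linear.  Sex is a male-vs-female indicator (unknown-sex reports are
excluded upstream).  The two co-medication confounders are report-level
indicator flags: the drug set intersects the catalog's
movement-disorder-inducing (resp. -treating) list.

**Multiplicity.** `bonferroni_alpha(n, 0.05)` divides the family-wise
level by the number of comparisons; for the 58-drug family this is
0.000862, optionally rounded to the working threshold 0.001.  The
significance flag additionally requires aROR > 1 and ≥10 exposed cases —
disproportionality on a handful of reports is noise, not signal.

## Exclusion filtering

`apply_exclusions` removes, in a fixed order that the per-step counts in
the log depend on: (1) reports outside the configured year range; (2)
reports with missing age; (3) reports with implausible ("outlying") age —
default bounds 5 and 110 years, the lower anchored to the unreliability of
under-five reports in spontaneous-report systems, both configurable
because "outlying" has no canonical definition; (4) reports with unknown
sex; (5) reports listing more than one study antidepressant (the exposure
must be unambiguous; such reports are excluded, never reassigned).
Reports with an empty reaction list cannot exist in memory — they are
rejected at parse time — so "no detailed reaction" filtering happens at
the I/O boundary.  The filter is idempotent and its log counts sum to the
size difference.

## Restricted-period sensitivity analysis

For recently launched drugs, pooling over the whole database period
dilutes exposure against decades without the drug.
`sensitivity_restricted_period` refits the adjusted model on reports from
the drug's first-report year onward (configured in the catalog, or the
earliest observed report year of the drug otherwise).  Report year is
therefore a required field of every report.

## The drug catalog and term dictionary

The default term dictionary maps the nine movement-disorder subtypes to 30
pairwise-disjoint Preferred Terms (adapted from the Standardised MedDRA
Queries); matching is case-insensitive after whitespace trimming, at PT
level only (no Lowest-Level-Term expansion — the package matches the
strings it is given).  The default catalog partitions the 58 study
antidepressants into 19 tricyclics, 8 serotonin reuptake inhibitors, 8
MAO inhibitors and 23 "other" antidepressants following ATC convention
(N06AA → TCA, N06AB → SRI, N06AF/N06AG → MAOI, otherwise OTHER).  The
inducer/treater co-medication lists shipped as defaults are small,
documented placeholders (typical antipsychotics and antiparkinsonian
agents); both the lists and the class assignment are overridable from a
YAML configuration, and a strict mode checks declared class counts.

## The synthetic-data generator

Real spontaneous-report extractions cannot be redistributed, so the
generator produces datasets with the statistical structure the analysis
assumes.  Per report: year uniform over the configured span; latent sex
(female with probability 0.6826 among known, i.e. a female/male ratio of
2.15) and latent age (normal 50.9 ± 18.0 years truncated to [0, 110])
feed the outcome model and are masked afterwards (29% missing age, 5%
unknown sex); drug exposures are independent Bernoulli draws per drug
(database-wide shape, ~7.2% of reports exposed overall) or exactly one
antidepressant per report (extraction shape); inducer/treater
co-medications are Bernoulli indicators whose probability may depend on
exposure to a named drug — that dependence is how exposure-correlated
confounding is planted; case status per subtype is Bernoulli with logit
`baseline + planted effects + covariate effects` (age per decade centred
at 50, male indicator, inducer, treater); each case adds one PT drawn from
the subtype's dictionary list, and every report carries ≥1 background
reaction from a pool of unrelated common PTs so reaction sets are never
empty.

The database-wide configuration (`paper_shaped_config`) plants per-subtype
exposure effects between 1.49 and 10.37 on the odds-ratio scale over
background reporting rates between ~1e-4 and ~9e-3, and calibrates the
baseline odds (deterministically, by root-finding at construction, with an
analytic correction for the mean odds contribution of the covariates) so
that ~2.8% of exposed reports carry a movement disorder.  Per-drug
exposure prevalence is uniform across the 58 drugs — a deliberate
simplification; real prescribing is heavily skewed.

Randomness contract: one mandatory integer seed; every variable samples
from its own named substream spawned from the seed in a fixed order, so
generation is bit-reproducible and increasing `n_reports` extends a
dataset without changing earlier reports (tested).

**What passing tests do and do not show.**  The generator draws exposures
independently across drugs, subtypes independently given covariates, and
reports independently of each other; it does not emulate duplicate
reports, reporting-rate dynamics (e.g. the early-marketing reporting
peak), country or notifier reporting cultures, or indication bias.
Parameter recovery on generated data therefore validates the estimator
and the pipeline plumbing — it cannot validate the causal interpretation
of disproportionality statistics on real reporting data, where those
unmodelled mechanisms operate.

## Monte-Carlo validation

`recovery_harness` runs generate → exclude → fit over deterministic
derived seeds and reports, per planted effect, the mean adjusted and crude
estimates, CI coverage of the true odds ratio, and the significance-flag
rate (power, or type-I error under a null entry).  The shipped study
conditions: a null study (planted log-OR 0, 200 replicates of 20,000
reports — the focal drug at 30% of the extraction, outcome baseline 5%,
so each replicate has ~200 exposed cases) for CI coverage, and a
confounded study (planted log-OR 0.7, the focal drug raising inducer
co-medication prevalence from 0.05 to 0.35 with an inducer outcome effect
of 1.0, 20 replicates of 200,000 reports) in which the crude estimate is
biased upward (~2.8) while the adjusted model recovers exp(0.7) ≈ 2.01.
Replicate counts and sizes were chosen to make the Monte-Carlo binomial
margins quoted in the tests meaningful while keeping a full run in the
minutes range.

## Numerical and degenerate-input conventions

* Estimates are kept at full precision internally; display rounding is 2
  d.p. for estimates and CI bounds.
* An undefined result propagates as `estimate=None` with NaN p-value and
  a false significance flag; it is never silently dropped from result
  tables.
* The female/male ratio of an all-unknown-sex dataset is NaN, reported as
  undefined.
* Ties in subtype PT sampling cannot occur (one PT per case draw); PT
  list order is canonicalized by sorting so results do not depend on set
  iteration order.
* Categorical breakdowns in `summarize_dataset` always include their
  unknown category and sum to the dataset size.

## Known limitations

* Adjusted numeric results from the original confidential extraction are
  not reproducible here; the adjusted tier is validated by parameter
  recovery on generated data instead.
* PT matching is exact (case-insensitive) string matching; misspelled or
  LLT-coded reactions in real files will not match.
* The default inducer/treater lists are placeholders; analyses on real
  data must configure proper ATC-derived lists.
* The Wald interval undercovers for very small cell counts; the ≥10
  exposed-case rule guards the significance flag, but reported CIs for
  tiny cells should be read with care.
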