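import math

import pytest

from pvror import (
    AnalysisDesign,
    Dataset,
    ExclusionCriteria,
    apply_exclusions,
    build_table,
    class_comparison,
    crude_ror,
    drug_comparison,
    fit_adjusted_ror,
    is_case,
    results_to_wide,
    sensitivity_restricted_period,
)
from pvror.adjusted_model import exposure_set
from pvror.dictionaries import CLASSES
from pvror.synthetic_data import confounded_config, generate, null_config


@pytest.fixture(scope="module")
def analyzed(catalog_module):
    """Excluded (analysis-ready) extraction-shaped dataset, one seed."""
    ds = generate(confounded_config(n_reports=60_000, seed=1234))
    out, _ = apply_exclusions(ds, ExclusionCriteria(), catalog_module)
    return out


@pytest.fixture(scope="module")
def catalog_module():
    from pvror import default_drug_catalog

    return default_drug_catalog()


@pytest.fixture(scope="module")
def dictionary_module():
    from pvror import default_term_dictionary

    return default_term_dictionary()


class TestFitAdjustedRor:
    def test_zero_covariates_reproduce_crude_ror(
        self, analyzed, dictionary_module, catalog_module
    ):
        """Nested-model identity: the exposure-only logistic fit equals the
        2x2 cross-product estimate to 1e-6 relative."""
        design = AnalysisDesign(
            outcome_subtype="tremor", exposure="drug:citalopram", covariates=()
        )
        res, diag = fit_adjusted_ror(
            analyzed, design, dictionary_module, catalog_module
        )
        codes = exposure_set("drug:citalopram", catalog_module)
        table = build_table(
            analyzed,
            exposed=lambda r: bool(r.drugs_casefolded() & codes),
            case=lambda r: is_case(r, "tremor", dictionary_module),
        )
        crude = crude_ror(table)
        assert diag.converged
        assert math.isclose(res.estimate, crude.estimate, rel_tol=1e-6)
        assert math.isclose(res.ci_low, crude.ci_low, rel_tol=1e-4)
        assert res.n_exposed_cases == table.a

    def test_exposure_estimate_invariant_to_covariate_order(
        self, analyzed, dictionary_module, catalog_module
    ):
        orders = [
            ("age", "sex", "inducer", "treater"),
            ("treater", "inducer", "sex", "age"),
        ]
        estimates = []
        for cov in orders:
            design = AnalysisDesign(
                outcome_subtype="tremor", exposure="drug:citalopram", covariates=cov
            )
            res, _ = fit_adjusted_ror(analyzed, design, dictionary_module, catalog_module)
            estimates.append(res.estimate)
        assert math.isclose(estimates[0], estimates[1], rel_tol=1e-10)

    def test_planted_effect_recovered_and_crude_biased_upward(
        self, analyzed, dictionary_module, catalog_module
    ):
        """With an inducer co-medication both more frequent under the
        exposure and harmful for the outcome, the crude estimate overshoots
        the planted odds ratio while the adjusted one recovers it."""
        truth = math.exp(0.7)
        design = AnalysisDesign(outcome_subtype="tremor", exposure="drug:citalopram")
        adjusted, diag = fit_adjusted_ror(
            analyzed, design, dictionary_module, catalog_module
        )
        crude_design = AnalysisDesign(
            outcome_subtype="tremor", exposure="drug:citalopram", covariates=()
        )
        crude, _ = fit_adjusted_ror(
            analyzed, crude_design, dictionary_module, catalog_module
        )
        assert diag.converged
        assert abs(adjusted.estimate - truth) / truth < 0.15
        assert crude.estimate > adjusted.estimate

    def test_age_band_coding_gives_similar_exposure_estimate(
        self, analyzed, dictionary_module, catalog_module
    ):
        cont, _ = fit_adjusted_ror(
            analyzed,
            AnalysisDesign(outcome_subtype="tremor", exposure="drug:citalopram"),
            dictionary_module,
            catalog_module,
        )
        bands, _ = fit_adjusted_ror(
            analyzed,
            AnalysisDesign(
                outcome_subtype="tremor",
                exposure="drug:citalopram",
                age_coding="bands",
            ),
            dictionary_module,
            catalog_module,
        )
        assert abs(math.log(bands.estimate) - math.log(cont.estimate)) < 0.1

    def test_empty_cell_yields_undefined(self, dictionary_module, catalog_module, make):
        # no exposed case -> a = 0 -> undefined, no fit attempted
        ds = Dataset(
            reports=[
                make(report_id="a", drugs=("citalopram",), reactions=("Nausea",)),
                make(report_id="b", drugs=("sertraline",), reactions=("Tremor",)),
                make(report_id="c", drugs=("sertraline",), reactions=("Nausea",)),
            ]
        )
        design = AnalysisDesign(
            outcome_subtype="tremor", exposure="drug:citalopram", covariates=()
        )
        res, diag = fit_adjusted_ror(ds, design, dictionary_module, catalog_module)
        assert not res.defined
        assert not diag.converged and "empty" in diag.note

    def test_separation_is_a_documented_error_state(
        self, dictionary_module, catalog_module, make
    ):
        # age perfectly separates cases from non-cases
        reports = [
            make(
                report_id=f"S{i}",
                age=70.0 if i % 2 else 30.0,
                drugs=("citalopram",) if i < 10 else ("sertraline",),
                reactions=("Tremor",) if i % 2 else ("Nausea",),
            )
            for i in range(20)
        ]
        design = AnalysisDesign(
            outcome_subtype="tremor", exposure="drug:citalopram", covariates=("age",)
        )
        res, diag = fit_adjusted_ror(
            Dataset(reports=reports), design, dictionary_module, catalog_module
        )
        assert not res.defined
        assert not diag.converged and diag.note

    def test_missing_covariate_data_rejected(
        self, dictionary_module, catalog_module, make
    ):
        ds = Dataset(reports=[make(report_id="m", age=None)])
        design = AnalysisDesign(outcome_subtype="tremor", exposure="drug:citalopram")
        with pytest.raises(ValueError, match="exclusions"):
            fit_adjusted_ror(ds, design, dictionary_module, catalog_module)


class TestComparisons:
    def test_class_comparison_covers_4_by_9_grid(
        self, analyzed, dictionary_module, catalog_module
    ):
        out = class_comparison(analyzed, dictionary_module, catalog_module)
        assert len(out) == 4 * 9
        assert set(out["exposure"]) == set(CLASSES)

    def test_drug_rows_follow_catalog_order_and_absent_drug_is_undefined(
        self, dictionary_module, catalog_module, make
    ):
        reports = [
            make(
                report_id=f"D{i}",
                drugs=("citalopram",) if i % 2 else ("mirtazapine",),
                reactions=("Tremor",) if i % 3 else ("Nausea",),
            )
            for i in range(60)
        ]
        out = drug_comparison(Dataset(reports=reports), dictionary_module, catalog_module)
        assert len(out) == 58 * 9
        assert list(out["exposure"].unique()) == list(catalog_module.order)
        absent = out[out["exposure"] == "phenelzine"]
        assert absent["estimate"].isna().all()

    def test_wide_presentation_shape(self, dictionary_module, catalog_module, make):
        reports = [
            make(
                report_id=f"W{i}",
                drugs=("citalopram",) if i % 2 else ("amitriptyline",),
                reactions=("Tremor",) if i % 3 else ("Nausea",),
                age=30.0 + i,
                sex="female" if i % 4 else "male",
            )
            for i in range(80)
        ]
        long = class_comparison(
            Dataset(reports=reports), dictionary_module, catalog_module
        )
        wide = results_to_wide(long)
        assert wide.shape == (4, 9)
        assert (wide.loc["MAOI"] == "-").all()  # class absent from the data


class TestSensitivity:
    def test_first_year_at_dataset_start_equals_unrestricted(
        self, analyzed, dictionary_module, catalog_module
    ):
        design = AnalysisDesign(outcome_subtype="tremor", exposure="drug:citalopram")
        full, _ = fit_adjusted_ror(analyzed, design, dictionary_module, catalog_module)
        first = min(r.year for r in analyzed)
        res, window = sensitivity_restricted_period(
            analyzed, "citalopram", design, dictionary_module, catalog_module
        )
        assert window[0] == first
        assert math.isclose(res.estimate, full.estimate, rel_tol=1e-12)

    def test_window_starts_at_drug_first_report(
        self, dictionary_module, catalog_module, make
    ):
        reports = [
            make(report_id=f"E{i}", year=2000 + i, drugs=("citalopram",),
                 reactions=("Tremor",) if i % 2 else ("Nausea",))
            for i in range(16)
        ] + [
            make(report_id=f"L{i}", year=2010 + i % 6, drugs=("vortioxetine",),
                 reactions=("Tremor",) if i % 2 else ("Nausea",))
            for i in range(16)
        ]
        design = AnalysisDesign(outcome_subtype="tremor", exposure="drug:vortioxetine")
        res, window = sensitivity_restricted_period(
            Dataset(reports=reports), "vortioxetine", design,
            dictionary_module, catalog_module,
        )
        assert window[0] == 2010

    def test_configured_first_year_overrides_observed(
        self, dictionary_module, make
    ):
        from pvror.dictionaries import DrugCatalog, default_drug_catalog

        base = default_drug_catalog()
        catalog = DrugCatalog(
            class_of=dict(base.class_of),
            inducers=base.inducers,
            treaters=base.treaters,
            first_year={"citalopram": 2005},
            order=base.order,
        )
        reports = [
            make(report_id=f"C{i}", year=1998 + i,
                 drugs=("citalopram",) if i % 2 else ("sertraline",),
                 reactions=("Tremor",) if i % 3 else ("Nausea",))
            for i in range(30)
        ]
        design = AnalysisDesign(outcome_subtype="tremor", exposure="drug:citalopram")
        _, window = sensitivity_restricted_period(
            Dataset(reports=reports), "citalopram", design, dictionary_module, catalog
        )
        assert window[0] == 2005

    def test_absent_drug_gives_undefined(self, dictionary_module, catalog_module, make):
        ds = Dataset(reports=[make(report_id="x")])
        design = AnalysisDesign(outcome_subtype="tremor", exposure="drug:phenelzine")
        res, window = sensitivity_restricted_period(
            ds, "phenelzine", design, dictionary_module, catalog_module
        )
        assert not res.defined and window is None
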