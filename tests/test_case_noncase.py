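import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvror import (
    ContingencyTable,
    Dataset,
    ExclusionCriteria,
    apply_exclusions,
    build_table,
    build_table_from_flags,
    is_case,
)
from pvror.synthetic_data import generate, paper_shaped_config


class TestIsCase:
    def test_oculogyric_crisis_is_dystonia(self, dictionary, make):
        assert is_case(make(reactions=("Oculogyric crisis",)), "dystonia", dictionary)

    def test_tremor_is_not_bruxism(self, dictionary, make):
        assert not is_case(make(reactions=("Tremor",)), "bruxism", dictionary)

    def test_report_can_be_case_for_several_subtypes(self, dictionary, make):
        r = make(reactions=("Akinesia", "Bruxism"))
        assert is_case(r, "parkinsonism", dictionary)
        assert is_case(r, "bruxism", dictionary)
        assert not is_case(r, "tics", dictionary)

    def test_matching_is_case_insensitive(self, dictionary, make):
        assert is_case(make(reactions=("AKATHISIA ",)), "akathisia", dictionary)

    def test_unknown_subtype_raises(self, dictionary, make):
        with pytest.raises(KeyError):
            is_case(make(), "chorea", dictionary)


class TestExclusions:
    def test_polytherapy_excluded(self, catalog, make):
        ds = Dataset(
            reports=[
                make(report_id="P1", drugs=("citalopram", "sertraline")),
                make(report_id="P2", drugs=("citalopram", "lithium")),
            ]
        )
        out, log = apply_exclusions(ds, ExclusionCriteria(), catalog)
        # two antidepressants -> out; one antidepressant plus comedication -> kept
        assert [r.report_id for r in out] == ["P2"]
        assert log.removed["polytherapy"] == 1

    def test_young_age_excluded(self, catalog, make):
        ds = Dataset(reports=[make(report_id="Y1", age=3.0)])
        out, log = apply_exclusions(ds, ExclusionCriteria(min_age=5), catalog)
        assert len(out) == 0 and log.removed["outlying_age"] == 1

    def test_missing_age_and_sex_excluded(self, catalog, make):
        ds = Dataset(
            reports=[
                make(report_id="M1", age=None),
                make(report_id="M2", sex="unknown"),
                make(report_id="M3"),
            ]
        )
        out, log = apply_exclusions(ds, ExclusionCriteria(), catalog)
        assert [r.report_id for r in out] == ["M3"]
        assert log.removed["missing_age"] == 1 and log.removed["missing_sex"] == 1

    def test_year_range_applied_first(self, catalog, make):
        ds = Dataset(reports=[make(report_id="O1", year=1960, age=None)])
        _, log = apply_exclusions(
            ds, ExclusionCriteria(year_range=(1990, 2016)), catalog
        )
        assert log.removed == {
            "year_range": 1,
            "missing_age": 0,
            "outlying_age": 0,
            "missing_sex": 0,
            "polytherapy": 0,
        }

    def test_inactive_criteria_are_identity(self, catalog, shaped_dataset):
        out, log = apply_exclusions(
            shaped_dataset, ExclusionCriteria.inactive(), catalog
        )
        assert len(out) == len(shaped_dataset)
        assert all(v == 0 for v in log.removed.values())

    def test_idempotent(self, catalog, shaped_dataset):
        criteria = ExclusionCriteria(year_range=(1980, 2016))
        once, log1 = apply_exclusions(shaped_dataset, criteria, catalog)
        twice, log2 = apply_exclusions(once, criteria, catalog)
        assert len(twice) == len(once)
        assert all(v == 0 for v in log2.removed.values())

    def test_log_sums_to_size_difference(self, catalog, shaped_dataset):
        _, log = apply_exclusions(shaped_dataset, ExclusionCriteria(), catalog)
        assert sum(log.removed.values()) == log.n_input - log.n_output


class TestBuildTable:
    def test_one_report_per_cell(self, make):
        ds = Dataset(
            reports=[
                make(report_id="a", drugs=("x",), reactions=("Tremor",)),
                make(report_id="b", drugs=("x",), reactions=("Nausea",)),
                make(report_id="c", drugs=("y",), reactions=("Tremor",)),
                make(report_id="d", drugs=("y",), reactions=("Nausea",)),
            ]
        )
        t = build_table(
            ds,
            exposed=lambda r: "x" in r.drugs,
            case=lambda r: "Tremor" in r.reactions,
        )
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_all_exposed_cases(self, make):
        ds = Dataset(reports=[make(report_id=str(i)) for i in range(5)])
        t = build_table(ds, exposed=lambda r: True, case=lambda r: True)
        assert (t.a, t.b, t.c, t.d) == (5, 0, 0, 0)

    def test_matches_loop_oracle_on_generated_data(self, dictionary, catalog):
        ds = generate(paper_shaped_config(n_reports=10_000, seed=5))
        ads = catalog.antidepressants
        exposed = lambda r: bool(r.drugs_casefolded() & ads)
        case = lambda r: is_case(r, "tremor", dictionary)
        t = build_table(ds, exposed, case)
        a = b = c = d = 0
        for r in ds:  # one report at a time
            if exposed(r):
                if case(r):
                    a += 1
                else:
                    b += 1
            elif case(r):
                c += 1
            else:
                d += 1
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
        assert t.n == len(ds)

    def test_order_invariance(self, dictionary, catalog, shaped_dataset):
        ads = catalog.antidepressants
        exposed = lambda r: bool(r.drugs_casefolded() & ads)
        case = lambda r: is_case(r, "tremor", dictionary)
        forward = build_table(shaped_dataset, exposed, case)
        reversed_ds = Dataset(reports=list(reversed(shaped_dataset.reports)))
        assert build_table(reversed_ds, exposed, case) == forward

    def test_exposure_partition_shares_case_margin(self, dictionary, catalog, shaped_dataset):
        """Splitting exposure into a predicate and its complement gives two
        tables with the same case total whose exposed margins tile the
        dataset."""
        case = lambda r: is_case(r, "dystonia", dictionary)
        pred = lambda r: bool(r.drugs_casefolded() & catalog.antidepressants)
        t1 = build_table(shaped_dataset, pred, case)
        t2 = build_table(shaped_dataset, lambda r: not pred(r), case)
        assert t1.n_cases == t2.n_cases
        assert t1.n_exposed + t2.n_exposed == len(shaped_dataset)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)

    @settings(derandomize=True, max_examples=50)
    @given(
        flags=st.lists(
            st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=200
        )
    )
    def test_cells_partition_any_flag_sequence(self, flags):
        exp, cas = zip(*flags)
        t = build_table_from_flags(np.array(exp), np.array(cas))
        assert t.n == len(flags)
        assert t.n_exposed == sum(exp)
        assert t.n_cases == sum(cas)
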