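import pytest

from pvror import (
    Dataset,
    Report,
    default_drug_catalog,
    default_term_dictionary,
)
from pvror.synthetic_data import generate, paper_shaped_config


def make_report(
    report_id="R1",
    year=2005,
    age=40.0,
    sex="female",
    serious="no",
    drugs=("citalopram",),
    reactions=("Nausea",),
    country=None,
    notifier=None,
):
    return Report(
        report_id=report_id,
        year=year,
        age=age,
        sex=sex,
        country=country,
        serious=serious,
        notifier=notifier,
        drugs=frozenset(drugs),
        reactions=frozenset(reactions),
    )


@pytest.fixture(scope="session")
def dictionary():
    return default_term_dictionary()


@pytest.fixture(scope="session")
def catalog():
    return default_drug_catalog()


@pytest.fixture(scope="session")
def shaped_dataset():
    """Small database-shaped synthetic dataset shared across tests."""
    return generate(paper_shaped_config(n_reports=3000, seed=42))


@pytest.fixture()
def make():
    return make_report
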