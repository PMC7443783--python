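import pandas as pd
import pytest

from oaburden.life_tables import default_life_tables
from oaburden.pipeline import link_deaths, select_cohort
from oaburden.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def tables():
    return default_life_tables()


@pytest.fixture(scope="session")
def small_synthetic():
    """A 2000-patient synthetic cohort with a handful of deaths."""
    return generate(SyntheticConfig(n_cases=2000, seed=42, p_oa_death=0.002))


@pytest.fixture(scope="session")
def small_cohort(small_synthetic):
    syn = small_synthetic
    sel = select_cohort(syn.records, year=2016)
    return link_deaths(sel.cohort, syn.deaths)


def make_records(rows):
    cols = ["patient_id", "sex", "age", "visit_date", "icd10", "setting",
            "network", "prior_treatment"]
    defaults = {
        "sex": "female", "age": 60, "visit_date": "2016-06-01",
        "icd10": "M17", "setting": "outpatient",
        "network": "Metropolitan Lima", "prior_treatment": False,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows], columns=cols)
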