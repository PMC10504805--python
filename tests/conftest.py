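import numpy as np
import pandas as pd
import pytest

from edenrisk import SyntheticConfig, generate_cohort
from edenrisk.cohort import RECORD_COLUMNS


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-record synthetic cohort under the default study conditions."""
    return generate_cohort(SyntheticConfig(n=2000, seed=20060101))


@pytest.fixture(scope="session")
def big_cohort():
    """A 100,000-record cohort for parameter-recovery and marginal checks."""
    return generate_cohort(SyntheticConfig(n=100_000, seed=20180101))


def make_raw_record(**overrides) -> dict:
    """A fully complete raw participant record, overridable per field."""
    base = {
        "id": "p0",
        "dentate_2006": True,
        "edentulous_2018": False,
        "age": 67,
        "race": "Caucasian",
        "gender": "Female",
        "education": "CollegePlus",
        "smoking": "Never",
        "dental_visit_2y": "Within2y",
        "alcohol": "Drinks",
        "cognition_score": 30,
        "self_rated_health": "GoodPlus",
        "lonely": "No",
        "income": "Ge75k",
    }
    base.update(overrides)
    return base


def raw_frame(records) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=list(RECORD_COLUMNS))
    return df[list(RECORD_COLUMNS)]
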