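import numpy as np
import pandas as pd
import pytest

from ewascan.codebook import (CaseDefinition, Codebook, CohortTable,
                              FactorDescriptor, classify_cases)


def make_cohort(n=600, seed=0, cohort_id="c1", n_strata=6, psus=3,
                prevalence=0.1, exposures=None):
    """Small hand-rolled cohort frame for unit tests (independent of the
    package's own simulator)."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "fbg": np.where(rng.random(n) < prevalence, 140.0, 100.0),
        "age": rng.uniform(20, 80, n),
        "sex": rng.choice(["male", "female"], n),
        "bmi": rng.uniform(18, 40, n),
        "ethnicity": rng.choice(["white", "black", "mexican", "other"], n),
        "poverty_index": rng.uniform(0, 5, n),
        "stratum": rng.integers(n_strata, size=n),
        "psu": rng.integers(psus, size=n),
        "weight": rng.lognormal(9.0, 0.4, n),
    })
    exposures = exposures or {}
    for sym, values in exposures.items():
        df[sym] = values
    return CohortTable(cohort_id=cohort_id, data=df,
                       exposure_columns=tuple(exposures))


@pytest.fixture
def lognormal_cohort():
    """Classified cohort with two independent lognormal exposures."""
    rng = np.random.default_rng(42)
    n = 800
    table = make_cohort(n=n, seed=42, exposures={
        "EXPA": rng.lognormal(1.0, 0.8, n),
        "EXPB": rng.lognormal(0.0, 1.2, n),
    })
    return classify_cases(table, CaseDefinition())


@pytest.fixture
def two_factor_codebook():
    return Codebook([
        FactorDescriptor(symbol="EXPA", env_class="nutrients",
                         units="ug/dL"),
        FactorDescriptor(symbol="EXPB", env_class="heavy metals",
                         units="ng/mL"),
    ])
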