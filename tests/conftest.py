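import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gendiag import synthetic

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def life_table():
    return synthetic.generate_life_table((16, 64), (2002, 2019))


@pytest.fixture(scope="session")
def default_cohort(life_table):
    """A 20 000-patient cohort under the default study conditions, with the
    generator's latent score exposed as the gender score."""
    cohort = synthetic.generate_cohort(synthetic.default_config(20_000, seed=1),
                                       life_table)
    return cohort.assign(gender_score=cohort["latent_score"])


@pytest.fixture()
def toy_mortality_cohort():
    """Six severe patients covering death mid-window, day-0 death, death on
    the last day and censoring."""
    return pd.DataFrame({
        "patient_id": [f"T{i}" for i in range(6)],
        "sex": [0, 1, 0, 1, 0, 1],
        "age": [20, 30, 40, 50, 60, 25],
        "event_year": [2010] * 6,
        "death_day": [3, np.nan, 0, 30, np.nan, 12],
        "adg_score": [1.0, 2.0, 3.0, 1.0, 2.0, 0.0],
        "rural": [0, 1, 0, 0, 1, 0],
        "income_quintile": [1, 2, 3, 4, 5, 3],
        "mechanism": ["falls", "struck", "other", "falls", "cyclist",
                      "motor_vehicle"],
        "severity": ["severe"] * 6,
        "survival_known": [True] * 6,
    })


def severe_only_config(n=5000, seed=0, sex_beta=float(np.log(1.5)),
                       gender_beta=0.0, intercept=5.7):
    """Severe-only cohort with known mortality effects and no missingness:
    the workhorse of the parameter-recovery checks."""
    return synthetic.SimulationConfig(
        n_patients=n, severity_probs=(0.0, 0.0, 0.0, 1.0),
        prob_unknown_survival=0.0, missing_los_rate=0.0, missing_adg_rate=0.0,
        code_catalog=synthetic.default_code_catalog(),
        mortality_betas={"intercept": intercept, "sex": sex_beta,
                         "gender_score": gender_beta},
        seed=seed)


def acute_only_config(n=20_000, seed=0, discharge_betas=None,
                      sublocation_probs=(0.6, 0.2, 0.1, 0.1)):
    """All-acute, all-mild cohort (nobody dies) with known discharge
    coefficients and no missingness."""
    if discharge_betas is None:
        discharge_betas = synthetic.default_discharge_betas()
    return synthetic.SimulationConfig(
        n_patients=n, prop_acute=1.0, severity_probs=(0.0, 1.0, 0.0, 0.0),
        prob_unknown_survival=0.0, missing_los_rate=0.0, missing_adg_rate=0.0,
        code_catalog=synthetic.default_code_catalog(),
        discharge_betas=discharge_betas,
        other_sublocation_probs=sublocation_probs,
        seed=seed)
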