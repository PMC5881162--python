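import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from efvbayes import PHENOTYPES, CohortDataset, Phenotype, calibrate_population, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def specs():
    """Population specs calibrated to the default (published) PK targets."""
    return calibrate_population()


@pytest.fixture(scope="session")
def small_training(specs):
    """Mixed labelled cohort, 2 trials x 300 subjects, at the five candidate
    sampling times — big enough for a stable classifier, fast to build."""
    return simulate_cohort(
        specs,
        phenotype_mix={ph: 1.0 for ph in PHENOTYPES},
        n_trials=2,
        n_per_trial=300,
        seed=101,
    )


def make_cohort(records, dose=600.0):
    """Tiny hand-written cohort from (subject, phenotype, time, conc) tuples."""
    df = pd.DataFrame(records, columns=["subject_id", "phenotype", "time_h", "conc_ng_ml"])
    df["phenotype"] = df["phenotype"].astype("string")
    return CohortDataset(df=df, dose=dose)


@pytest.fixture
def tiny_24h_cohort():
    """Three phenotypes with a handful of 24 h concentrations each."""
    rows = []
    for ph, concs in (
        ("EM", [120, 260, 410, 180]),
        ("IM", [620, 700, 540]),
        ("PM", [1130, 1080, 940]),
    ):
        for i, c in enumerate(concs):
            rows.append((f"{ph}s{i}", ph, 24.0, float(c)))
    return make_cohort(rows)
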