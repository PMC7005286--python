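import numpy as np
import pandas as pd
import pytest

from binsurv import (
    FeatureSchema,
    SimulationScenario,
    SurvivalData,
    TimeBinning,
    simulate,
)


def make_cohort(durations, events, covariates=None, schema=None):
    """Tiny SurvivalData builder for hand-constructed examples."""
    durations = np.asarray(durations, dtype=float)
    n = durations.size
    if covariates is None:
        rng = np.random.default_rng(0)
        covariates = pd.DataFrame({"x1": rng.standard_normal(n)})
        schema = FeatureSchema.from_pairs([("x1", "continuous")])
    return SurvivalData(covariates, durations, np.asarray(events, dtype=bool), schema)


@pytest.fixture
def toy6():
    """Six-subject cohort with a hand-computed Kaplan-Meier table.

    Durations/events: 1.5+, 2.5+, 0.5c, 2.2c, 4.0+, 4.5c (unit monthly bins,
    J = 5).  KM: S = (1, 0.8, 0.6, 0.6, 0.3).
    """
    return make_cohort([1.5, 2.5, 0.5, 2.2, 4.0, 4.5],
                       [True, True, False, False, True, False])


@pytest.fixture
def toy6_binning(toy6):
    return TimeBinning.from_durations(toy6.durations)


@pytest.fixture(scope="session")
def sim_small():
    """200-subject linear PH cohort with one real effect and ~70% censoring."""
    scenario = SimulationScenario(
        n_subjects=200, n_continuous=3, n_categorical=2,
        beta={"x1": 0.7}, seed=11, missing_rate=0.05,
    )
    data, truth = simulate(scenario)
    return data, truth


@pytest.fixture(scope="session")
def sim_two_cov():
    """500-subject cohort with two known continuous effects, no missingness."""
    scenario = SimulationScenario(
        n_subjects=500, n_continuous=2, n_categorical=0,
        beta={"x1": 0.8, "x2": -0.5}, seed=7,
    )
    data, truth = simulate(scenario)
    return data, truth
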