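import numpy as np
import pandas as pd
import pytest

from polyscreen import (EconParams, RiskModel, ScreeningCEA, ScreeningEffects,
                        Strategy, SynthConfig, generate_rates)
from polyscreen.lifetable import RateTable


@pytest.fixture(scope="session")
def risk_model():
    return RiskModel()


@pytest.fixture(scope="session")
def synth_rates():
    """Default synthetic rate table, calibrated to the 2.6%/7.1% anchors."""
    return generate_rates(SynthConfig(seed=1))


@pytest.fixture
def effects():
    return ScreeningEffects()


@pytest.fixture
def econ():
    return EconParams()


@pytest.fixture
def neutral_effects():
    """Screening effects switched off: scenarios must coincide."""
    return ScreeningEffects(rr_mortality=1.0, rr_incidence=1.0, rr_advanced=1.0,
                            overdiagnosis_intercept=0.0, overdiagnosis_slope=0.0)


@pytest.fixture(scope="session")
def toy_rates():
    """A 5-age table (85-89, run to 90) small enough for brute force."""
    return RateTable(pd.DataFrame({
        "age": [85, 86, 87, 88, 89],
        "pc_incidence": [0.02, 0.022, 0.024, 0.026, 0.028],
        "pc_mortality": [0.008, 0.009, 0.010, 0.011, 0.012],
        "other_mortality": [0.06, 0.07, 0.08, 0.09, 0.10],
        "population_weight": [0.0, 0.0, 0.0, 0.0, 0.0],
    }))


@pytest.fixture(scope="session")
def det_results(synth_rates):
    """Deterministic full-grid evaluation, shared across tests."""
    cea = ScreeningCEA(synth_rates)
    return cea.fit()


def make_rates(ages, inc, pcm, oth, weights=None):
    n = len(ages)
    return RateTable(pd.DataFrame({
        "age": ages,
        "pc_incidence": np.broadcast_to(inc, n),
        "pc_mortality": np.broadcast_to(pcm, n),
        "other_mortality": np.broadcast_to(oth, n),
        "population_weight": np.zeros(n) if weights is None else weights,
    }))
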