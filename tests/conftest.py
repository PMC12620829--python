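import numpy as np
import pytest

from adaqsp.config import (
    DrugParameters,
    PhysiologyParameters,
    Regimen,
    SamplingSchedule,
)
from adaqsp.fixtures import get_scenario, run_scenario

TRIAL_SEED = 20240901


@pytest.fixture(scope="session")
def iv_drug():
    return DrugParameters(
        name="iv_test",
        molecular_weight_g_per_mol=150_000.0,
        clearance_mean_L_per_h=0.05,
        route="IV_bolus",
    )


@pytest.fixture(scope="session")
def sc_drug():
    return DrugParameters(
        name="sc_test",
        molecular_weight_g_per_mol=150_000.0,
        clearance_mean_L_per_h=0.01,
        route="SC",
        bioavailability=0.7,
        ka_per_h=0.01,
    )


@pytest.fixture(scope="session")
def physiology():
    return PhysiologyParameters()


@pytest.fixture(scope="session")
def single_iv_regimen():
    return Regimen(dose_mg=100.0, interval_h=336.0, n_doses=1)


@pytest.fixture(scope="session")
def high_risk_scenario():
    return get_scenario("high_risk_drug")


@pytest.fixture(scope="session")
def low_risk_scenario():
    return get_scenario("low_risk_drug")


@pytest.fixture(scope="session")
def trough_schedule():
    troughs = [336.0 * k for k in range(1, 7)]
    return SamplingSchedule(
        ada_times_h=troughs, pk_times_h=troughs, final_time_h=2016.0
    )


@pytest.fixture(scope="session")
def high_risk_trial_250():
    """Seeded 250-subject virtual trial of the immunogenic scenario."""
    return run_scenario("high_risk_drug", n=250, seed=TRIAL_SEED)


@pytest.fixture(scope="session")
def low_risk_trial_250():
    """Seeded 250-subject virtual trial of the weakly immunogenic scenario."""
    return run_scenario("low_risk_drug", n=250, seed=TRIAL_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
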