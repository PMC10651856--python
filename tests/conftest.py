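
import pytest

from ovupredict.cycle_data import Cycle, CycleObservation, MonitoringDataset
from ovupredict.synthetic_cycles import default_simulation_params, simulate_cohort


def make_obs(
    day,
    participant="P1",
    cycle="C1",
    lh=None,
    estrogen=None,
    progesterone=None,
    follicle=None,
    endometrium=None,
    assessed=True,
):
    return CycleObservation(
        participant_id=participant,
        cycle_id=cycle,
        cycle_day=day,
        lh=lh,
        estrogen=estrogen,
        progesterone=progesterone,
        follicle_mm=follicle,
        endometrium_mm=endometrium,
        follicle_assessed=assessed,
    )


def make_cycle(observations, ovulation_cycle_day=None):
    return Cycle(
        observations=tuple(observations), ovulation_cycle_day=ovulation_cycle_day
    )


def make_dataset(*cycles, provenance="fixture"):
    return MonitoringDataset(cycles=tuple(cycles), provenance=provenance)


@pytest.fixture(scope="session")
def default_params():
    return default_simulation_params()


@pytest.fixture(scope="session")
def cohort_118(default_params):
    return simulate_cohort(default_params, 118, rng_seed=1)


@pytest.fixture(scope="session")
def cohort_500(default_params):
    return simulate_cohort(default_params, 500, rng_seed=7)


@pytest.fixture(scope="session")
def cohort_2000(default_params):
    return simulate_cohort(default_params, 2000, rng_seed=1)
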