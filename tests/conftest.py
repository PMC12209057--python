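import numpy as np
import pytest
from hypothesis import settings

import rxpersist as rp
from rxpersist.synthetic import SimulationConfig, generate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def brute_force_covered_days(fill_days, supplies, followup=365):
    """Independent oracle: mark each covered day in a boolean array."""
    days = np.zeros(followup, dtype=bool)
    for day, supply in zip(fill_days, supplies):
        if 0 <= day < followup:
            days[day : min(day + int(supply), followup)] = True
    return int(days.sum())


@pytest.fixture(scope="session")
def worked_bundle():
    return rp.make_worked_fixture()


@pytest.fixture(scope="session")
def worked_cohort(worked_bundle):
    return rp.build_cohort(worked_bundle)


@pytest.fixture(scope="session")
def synth_population():
    """Mid-sized synthetic population shared across tests (seed fixed)."""
    bundle, truth = generate(SimulationConfig(n_patients=5000, seed=20201))
    return bundle, truth


@pytest.fixture(scope="session")
def synth_cohort(synth_population):
    bundle, _ = synth_population
    cohort, flow = rp.build_cohort(bundle)
    return bundle, cohort, flow
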