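import numpy as np
import pytest

from sodiumcea import (
    build_default_interventions,
    generate_model_inputs,
    run_cohort,
)
from sodiumcea.effect_chain import EffectChainParams


@pytest.fixture(scope="session")
def inputs():
    """Default synthetic world (seed 1, 2.3 million adults)."""
    return generate_model_inputs(seed=1)


@pytest.fixture(scope="session")
def specs():
    return build_default_interventions()


def _pick(specs, iid, mode):
    return next(s for s in specs if s.id == iid and s.mode == mode)


@pytest.fixture(scope="session")
def full_mandatory(specs):
    return _pick(specs, 1, "mandatory")


@pytest.fixture(scope="session")
def full_voluntary(specs):
    return _pick(specs, 1, "voluntary")


@pytest.fixture(scope="session")
def effect():
    return EffectChainParams()


@pytest.fixture(scope="session")
def comparator_traj(inputs):
    return run_cohort(inputs)


@pytest.fixture()
def zero_event_inputs(inputs):
    """World without any disease events or deaths (degenerate checks)."""
    import copy

    z = copy.deepcopy(inputs)
    for d in ("chd", "stroke"):
        z.epi.incidence[d][:] = 0.0
        z.epi.case_fatality[d][:] = 0.0
        z.epi.prevalence[d][:] = 0.0
    z.epi.background_mortality[:] = 0.0
    return z
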