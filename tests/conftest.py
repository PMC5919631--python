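import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import exermet as xm

hyp_settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_params() -> xm.ModelParameters:
    return xm.reference_parameters()


@pytest.fixture(scope="session")
def study3_protocol() -> xm.ExerciseProtocol:
    return xm.build_protocol(3)


@pytest.fixture(scope="session")
def study3_subject() -> xm.SubjectProfile:
    return xm.reference_subject(3)


@pytest.fixture(scope="session")
def study3_settings() -> xm.SimulationSettings:
    return xm.SimulationSettings(t0=0.0, t_end=210.0)


@pytest.fixture(scope="session")
def study3_trajectory(study3_subject, study3_protocol, ref_params, study3_settings):
    """The canonical 60-min bout at Tv=60 with 30-min baseline, 120-min recovery."""
    return xm.simulate(study3_subject, study3_protocol, ref_params,
                       settings=study3_settings)


@pytest.fixture
def single_bout() -> xm.ExerciseProtocol:
    return xm.ExerciseProtocol.single_bout(tv=60.0, t_start=0.0, t_end=60.0)
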