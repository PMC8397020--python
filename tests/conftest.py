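import numpy as np
import pytest

from boldperf import (AcquisitionProtocol, ParadigmSchedule, SubjectParams,
                      curve_params, default_phantom_geometry)

#: Published control-group gastrocnemius curve parameters (BL, overshoot, TTP).
CONTROL_GAS = dict(baseline=24.6, overshoot=1.49, ttp=48.0)
PAOD_GAS = dict(baseline=25.3, overshoot=0.59, ttp=111.0)
CONTROL_SOL = dict(baseline=20.8, overshoot=1.81, ttp=41.0)


@pytest.fixture(scope="session")
def schedule():
    return ParadigmSchedule()


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def geometry():
    return default_phantom_geometry((32, 32))


def make_subject(gas=None, sol=None, motion=None, noise_sigma=0.0,
                 subject_id="s1", group="control", abi=1.1):
    gas = curve_params(**(gas or CONTROL_GAS))
    sol = curve_params(**(sol or CONTROL_SOL))
    return SubjectParams(subject_id=subject_id, group=group, abi=abi,
                         region_params={"gastrocnemius": gas, "soleus": sol,
                                        "bone": 10.0},
                         motion_trace=motion, noise_sigma=noise_sigma)


@pytest.fixture()
def noiseless_subject():
    return make_subject()
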