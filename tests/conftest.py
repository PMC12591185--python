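import math

import numpy as np
import pytest

from swimchemo.hydrodynamics import (
    L_MAX,
    L_MIN,
    THETA_A_MAX,
    THETA_A_MIN,
    HydroParams,
    SwimmerState,
)


@pytest.fixture(scope="session")
def hydro_params():
    return HydroParams()


def random_state(rng) -> SwimmerState:
    return SwimmerState(
        r1=rng.normal(scale=2.0, size=2),
        theta1=rng.uniform(-math.pi, math.pi),
        L1=rng.uniform(L_MIN, L_MAX),
        L2=rng.uniform(L_MIN, L_MAX),
        thetaA=rng.uniform(THETA_A_MIN, THETA_A_MAX),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
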