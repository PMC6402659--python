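import numpy as np
import pytest

from posturesim import (ControllerParams, FixtureSpec, HillCurves,
                        MuscleParams, make_fixture)


@pytest.fixture(scope="session")
def curves():
    return HillCurves()


@pytest.fixture
def simple_muscle():
    """Single-joint muscle with round numbers for hand calculations."""
    return MuscleParams(
        name="m", F0=100.0, L_opt=0.1, V_max=0.5, L_ref=0.3, L_slack=0.2,
        moment_arms=(0.05,), group="ankle_extensor",
    )


@pytest.fixture(scope="session")
def single_link():
    return make_fixture(FixtureSpec("single_link"))


@pytest.fixture(scope="session")
def sagittal_3link():
    return make_fixture(FixtureSpec("sagittal_3link"))


@pytest.fixture(scope="session")
def frontal_2link():
    return make_fixture(FixtureSpec("frontal_2link"))


@pytest.fixture
def two_muscle_controller(simple_muscle):
    """Controller over an antagonist pair of the simple muscle."""
    antagonist = MuscleParams(
        name="n", F0=100.0, L_opt=0.1, V_max=0.5, L_ref=0.3, L_slack=0.2,
        moment_arms=(-0.05,), group="ankle_flexor",
    )
    muscles = [simple_muscle, antagonist]
    ctrl = ControllerParams(
        muscle_names=("m", "n"),
        u_ff=np.array([0.1, 0.1]),
        k_p={"ankle_extensor": 0.5, "ankle_flexor": 0.5},
        k_d={"ankle_extensor": 0.2, "ankle_flexor": 0.2},
        group_map={"m": "ankle_extensor", "n": "ankle_flexor"},
        L0_MT=np.array([0.3, 0.3]),
    )
    return muscles, ctrl
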