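import warnings

import numpy as np
import pytest

import ssadapt as sa
from ssadapt import synthetic_data as sd

# zero residual variance on noise-free recovery fits is expected and warned
warnings.filterwarnings("ignore", message="zero residual variance")


@pytest.fixture(scope="session")
def exp1_schedule():
    return sa.build_schedule("exp1", seed=1)


@pytest.fixture(scope="session")
def srm_truth():
    return sd.EXP1_SRM_TRUTH


@pytest.fixture(scope="session")
def drm_truth():
    return sd.EXP1_DRM_TRUTH


@pytest.fixture(scope="session")
def mcsrm_truth():
    return sd.MCSRM4_TRUTH


@pytest.fixture(scope="session")
def compliance():
    return sa.unit_compliance()


def constant_schedule(mode: str, n: int, orientation: float = 0.0, mass: float = 0.01):
    """A minimal single-phase schedule (used by closed-form oracles)."""
    from ssadapt.schedules import Schedule, Trial

    trials = tuple(
        Trial(i, mode, orientation, "CW" if i % 2 == 0 else "CCW", mass, "phase", 0)
        for i in range(n)
    )
    return Schedule("exp1", trials, seed=0)


@pytest.fixture(scope="session")
def make_constant_schedule():
    return constant_schedule
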