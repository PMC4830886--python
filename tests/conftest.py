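import numpy as np
import pytest

from devtoxrank.transport import TranswellConfig


@pytest.fixture
def cfg() -> TranswellConfig:
    """Default 12-mm insert geometry (A=1.12 cm2, 0.5/1.5 ml, 0.2-ml samples, 50 uM)."""
    return TranswellConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


# representative true parameters per quantal model, mid-range BMC on a
# 0-60 uM grid; shared between recovery tests and the acceptance suite
TRUE_MODEL_PARAMS = {
    "quantal_linear": (0.03, 0.15),
    "loglogistic": (0.03, -3.0, 2.0),
    "logprobit": (0.03, -1.8, 1.2),
    "weibull": (0.03, 1.5, 0.05),
    "gamma": (0.03, 2.0, 0.4),
    "logistic": (-3.0, 0.35),
    "probit": (-1.8, 0.2),
    "multistage": (0.03, 0.05, 0.003),
}

RECOVERY_GRID = np.array([0.0, 0.5, 1.5, 5.0, 15.0, 30.0, 60.0])
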