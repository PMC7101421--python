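import numpy as np
import pytest

from cvai import BinarisationConfig, SyntheticSpec, run_pipeline
from cvai.synth import generate_eye


@pytest.fixture(scope="session")
def spec() -> SyntheticSpec:
    return SyntheticSpec()


@pytest.fixture(scope="session")
def bin_cfg() -> BinarisationConfig:
    return BinarisationConfig()


@pytest.fixture(scope="session")
def sample_eye(spec):
    """One thin-choroid (well-visible vasculature) synthetic eye."""
    return generate_eye(spec, thickness_um=150.0, group="normal", seed=3)


@pytest.fixture(scope="session")
def sample_result(sample_eye, bin_cfg):
    """Pipeline output on the sample eye, shared across tests."""
    return run_pipeline(sample_eye.image, bin_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
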