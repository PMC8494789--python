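import numpy as np
import pytest

from thalnet.synthetic_data import make_ground_truth, simulate_subject
from thalnet.volume_io import Mask


@pytest.fixture(scope="session")
def gt():
    """Standard 3-network ground truth (factor-0.5 decrease on component 0)."""
    return make_ground_truth(seed=3, group_effect={0: 0.5})


@pytest.fixture(scope="session")
def gt_noiseless():
    return make_ground_truth(seed=3, noise_sd=0.0, group_effect={0: 0.5})


@pytest.fixture(scope="session")
def cortex(gt):
    return Mask(data=gt.brain.data & ~gt.thalamus.data, affine=gt.affine)


@pytest.fixture(scope="session")
def control_subject(gt):
    vol, conf = simulate_subject(gt, "control", seed=42)
    return vol, conf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
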