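import numpy as np
import pytest

from nevusnet import synthgen as sg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benign_sample():
    spec = sg.random_spec("benign", np.random.default_rng(7), canvas=96,
                          patient_id="pb")
    return sg.make_sample(spec, 96, seed=7)


@pytest.fixture(scope="session")
def malignant_sample():
    spec = sg.random_spec("malignant", np.random.default_rng(11), canvas=96,
                          patient_id="pm")
    return sg.make_sample(spec, 96, seed=11)


def random_boxes(rng, n):
    """(n, 4) random valid centre-form boxes."""
    return np.stack([rng.uniform(-2, 2, n), rng.uniform(-2, 2, n),
                     rng.uniform(0.05, 3, n), rng.uniform(0.05, 3, n)],
                    axis=1)
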