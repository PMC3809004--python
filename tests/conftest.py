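import numpy as np
import pytest

from glycoarray import pipeline, synthetic_data as sd


@pytest.fixture(scope="session")
def gt_default():
    """Default ground truth: 500 um field, 3.9 um pixels, 200 um spot."""
    return sd.make_ground_truth()


@pytest.fixture(scope="session")
def discovery_default(gt_default):
    """Replicate-cube ion discovery on the default ground truth, seed 0."""
    return pipeline.discover_ions(gt_default, n_images=5, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
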