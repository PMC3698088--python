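import numpy as np
import pytest

from hlfseg.config import PipelineConfig, SlicConfig
from hlfseg.pipeline import process_image
from hlfseg.synthetic_data import SyntheticSpec, generate_synthetic_em


@pytest.fixture(scope="session")
def small_spec():
    """A 128x128 synthetic section spec used by most unit tests."""
    return SyntheticSpec(height=128, width=128, n_cells=6, seed=7)


@pytest.fixture(scope="session")
def small_image(small_spec):
    return generate_synthetic_em(small_spec)


@pytest.fixture(scope="session")
def small_config():
    # superpixel interval s = 8 on a 128x128 image
    return PipelineConfig(seed=7, slic=SlicConfig(k=256))


@pytest.fixture(scope="session")
def small_features(small_image, small_config):
    """Processed intermediates (superpixels, stacks, blocks) for reuse."""
    img, _ = small_image
    return process_image(img, small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
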