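import numpy as np
import pytest

from ihcquant.cell_segmentation import SegmentationParams
from ihcquant.compartment_scoring import PositivityConfig
from ihcquant.stain_separation import build_stain_matrix
from ihcquant.synthetic_data import ImageSpec, gen_core_image


@pytest.fixture(scope="session")
def hdab_matrix():
    return build_stain_matrix()


@pytest.fixture
def seg_params():
    return SegmentationParams()


@pytest.fixture
def pos_config():
    return PositivityConfig()


@pytest.fixture(scope="session")
def small_core():
    """A small rendered core with ground truth, shared across read-only tests."""
    spec = ImageSpec(height=320, width=320,
                     n_cells={"glandular": 40, "interstitial": 40}, seed=11)
    img, truth = gen_core_image(spec, keep_concentration=True)
    return spec, img, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
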