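import numpy as np
import pytest

from calpharm import LocoGenParams, gen_locomotion_block


@pytest.fixture(scope="session")
def small_loco_params():
    """A fast-to-generate session: few ROIs, short protocol untouched."""
    return LocoGenParams(n_rois=12, n_pre=4, n_post=5, seed=7)


@pytest.fixture(scope="session")
def small_block(small_loco_params):
    block, truth = gen_locomotion_block(small_loco_params)
    return block, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
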