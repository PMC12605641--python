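import numpy as np
import pytest

from segdecon.image_pp import preprocess
from segdecon.synthetic import SynthImageSpec, SynthStSpec, synth_hne, synth_st

# benchmark-scale tile: dense tissue with nucleus-sized brown artifacts
SPECKLED_SPEC = SynthImageSpec(size_px=256, n_nuclei=34, speckle_fraction=0.06)


@pytest.fixture(scope="session")
def speckled_tile():
    return synth_hne(SPECKLED_SPEC, seed=7)


@pytest.fixture(scope="session")
def speckled_preprocessed(speckled_tile):
    return preprocess(speckled_tile.rgb)


@pytest.fixture(scope="session")
def clean_tile():
    return synth_hne(
        SynthImageSpec(size_px=256, n_nuclei=30, speckle_fraction=0.0), seed=11
    )


@pytest.fixture(scope="session")
def st_instance():
    return synth_st(SynthStSpec(), seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
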