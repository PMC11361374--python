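import numpy as np
import pytest

import nepheno as ne


@pytest.fixture
def small_nucleus_spec():
    """Three clean (noiseless, unblurred) blebbed nuclei in a small frame."""
    return ne.NucleusImageSpec(
        image_size=(300, 300), n_nuclei=3, blebs_per_nucleus=1,
        bleb_radius_range=(8.0, 8.0), noise_sd=0.0, blur_sigma=0.0, seed=1,
    )


@pytest.fixture
def clean_pair(small_nucleus_spec):
    dapi, lamin, truth = ne.make_nucleus_image(small_nucleus_spec)
    return dapi, lamin, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
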