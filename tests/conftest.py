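import numpy as np
import pytest

import mammotex as mx


@pytest.fixture(scope="session")
def textured_image():
    """A mid-density textured image used across feature tests."""
    return mx.generate_mammogram(96, 96, 40.0, texture_scale=5, seed=11)


@pytest.fixture(scope="session")
def constant_image():
    """Constant gray 100 inside a full mask."""
    pixels = np.full((40, 40), 100, dtype=np.uint8)
    return mx.MammogramImage(pixels=pixels, mask=np.ones((40, 40), bool))


@pytest.fixture(scope="session")
def small_cohort():
    """A 4000-patient synthetic cohort from the reference generative model."""
    from dataclasses import replace
    params = replace(mx.REFERENCE_COHORT_PARAMS, n=4000, seed=202)
    return mx.generate_cohort(params)
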