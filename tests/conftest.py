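import numpy as np
import pytest

from woundtherm import GLCM, GLCMConfig


def random_glcm(rng: np.random.Generator, ng: int = 8, symmetric: bool = True) -> GLCM:
    """A valid random GLCM: non-negative, normalised, optionally symmetric."""
    p = rng.random((ng, ng))
    if symmetric:
        p = p + p.T
    p = p / p.sum()
    return GLCM(p=p, n_pairs=1000, config=GLCMConfig(n_levels=ng, symmetric=symmetric))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
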