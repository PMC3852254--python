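import numpy as np
import pytest

from distfreecr import PointSet, SimDesign, sample_bvn


@pytest.fixture(scope="session")
def bvn_10k() -> PointSet:
    """A fixed large bivariate-normal sample (r_xy = 0.5)."""
    return sample_bvn(SimDesign(design="normal", n=10_000, r_xy=0.5, seed=42))


@pytest.fixture(scope="session")
def bvn_2k() -> PointSet:
    """A fixed mid-size bivariate-normal sample (r_xy = 0.5)."""
    return sample_bvn(SimDesign(design="normal", n=2_000, r_xy=0.5, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
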