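import numpy as np
import pytest

from mvcoclust import (
    DatasetBundle,
    FamilySlab,
    PriorConfig,
    TruncationConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def prior():
    return PriorConfig()


def make_mixed_bundle(rng, n=6, d_gauss=3, d_pois=2, d_cat=2, missing=0.2):
    """Small mixed-family bundle with some masked cells."""
    slabs = []
    if d_gauss:
        slabs.append(FamilySlab("gaussian", rng.normal(size=(n, d_gauss)),
                                rng.random((n, d_gauss)) >= missing))
    if d_pois:
        slabs.append(FamilySlab("poisson", rng.poisson(3.0, size=(n, d_pois)).astype(float),
                                rng.random((n, d_pois)) >= missing))
    if d_cat:
        slabs.append(FamilySlab("categorical", rng.integers(0, 3, size=(n, d_cat)).astype(float),
                                rng.random((n, d_cat)) >= missing, n_levels=3))
    # guarantee no fully-missing column
    for slab in slabs:
        for j in range(slab.d):
            if not slab.mask[:, j].any():
                slab.mask[0, j] = True
    return DatasetBundle(slabs)


@pytest.fixture
def mixed_bundle(rng):
    return make_mixed_bundle(rng)


@pytest.fixture
def small_trunc():
    return TruncationConfig(V=2, G=2, K=2, n_restarts=1, max_iter=30, seed=7)
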