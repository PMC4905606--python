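import numpy as np
import pytest

from mgmsteps.core import MGMParameters, MixedDataset, _layout_for


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_params(p, levels, rng, scale=0.3, centered=True):
    """Random small MGM parameters with a safely positive beta diagonal."""
    layout = _layout_for(p, levels)
    v = rng.normal(scale=scale, size=layout.size)
    v[layout.s_bdiag] = np.abs(v[layout.s_bdiag]) + 1.0
    if centered:
        v[layout.s_rho] = layout.center_rho(v[layout.s_rho])
        v[layout.s_phioff] = layout.center_phi(v[layout.s_phioff])
    return layout.to_params(v)


def random_dataset(n, p, levels, rng):
    X = rng.normal(size=(n, p))
    Y = np.column_stack([rng.integers(0, L, size=n) for L in levels]) \
        if levels else np.zeros((n, 0), dtype=int)
    return MixedDataset(X, Y, levels)


@pytest.fixture
def small_params(rng):
    return random_params(3, (2, 3), rng)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(8, 3, (2, 3), rng)
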