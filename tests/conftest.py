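import numpy as np
import pytest

from duralseg.phantom import PhantomParams, generate_slice


@pytest.fixture(scope="session")
def small_params():
    """64x64 phantom geometry used throughout the desk-scale tests."""
    return PhantomParams(image_size=64, seed=0)


@pytest.fixture(scope="session")
def sdh_slice(small_params):
    return generate_slice("SDH", small_params)


@pytest.fixture(scope="session")
def edh_slice(small_params):
    return generate_slice("EDH", small_params)


def numeric_gradient(f, x, eps=1e-6):
    """Central finite differences of scalar f with respect to array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
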