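import numpy as np
import pytest

from modnet import autodiff as ad
from modnet import synthetic

ad.enable_fast_alloc()


@pytest.fixture(scope="session")
def sep_task():
    """A clearly separable 10-class vector task (class means 6 noise-sd apart)."""
    return synthetic.make_vector_task(
        n_classes=10, dims=100, n_per_class=600, separation=6.0,
        noise_sd=1.0, seed=7)


@pytest.fixture(scope="session")
def sep_test_set(sep_task):
    return synthetic.draw_samples(sep_task, n_per_class=100, seed=999)


@pytest.fixture(scope="session")
def small_bank():
    """A small glyph bank: 30 classes, 5 jittered samples each."""
    return synthetic.make_glyph_bank(30, samples_per_class=5, image_size=28,
                                     seed=1)


def finite_difference(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f with respect to array x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        fp = f()
        flat[i] = old - eps
        fm = f()
        flat[i] = old
        gflat[i] = (fp - fm) / (2 * eps)
    return g
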