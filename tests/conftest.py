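import numpy as np
import pytest

from risunet.phantoms import PhantomConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def numeric_gradient(f, x, eps=1e-6):
    """Central-difference gradient of scalar-valued f w.r.t. array x."""
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = f()
        x[idx] = orig - eps
        lo = f()
        x[idx] = orig
        grad[idx] = (hi - lo) / (2 * eps)
    return grad


@pytest.fixture(scope="session")
def phantom_cases():
    """The 12-case phantom cohort (8:2:2 split, master seed 39) shared by
    the end-to-end tests."""
    cases, manifest = generate_dataset(12, PhantomConfig(), master_seed=39)
    return cases, manifest
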