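import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def finite_difference_grad(f, x, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar-valued f w.r.t. tensor x."""
    g = np.zeros_like(x.data, dtype=np.float64)
    it = np.nditer(x.data, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = float(x.data[idx])
        x.data[idx] = orig + eps
        fp = f().item()
        x.data[idx] = orig - eps
        fm = f().item()
        x.data[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


def analytic_grad(f, x) -> np.ndarray:
    x.grad = None
    loss = f()
    loss.backward()
    return x.grad.copy()


def relative_error(a, b) -> float:
    return float(np.max(np.abs(a - b)) / (np.max(np.abs(b)) + 1e-8))
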