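import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_grad(f, args, wrt, eps=1e-6):
    """Central-difference gradient of scalar f(*args) w.r.t. args[wrt]."""
    a = np.asarray(args[wrt], dtype=np.float64)
    g = np.zeros_like(a)
    it = np.nditer(a, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        ap = [np.array(x, dtype=np.float64, copy=True) for x in args]
        am = [np.array(x, dtype=np.float64, copy=True) for x in args]
        ap[wrt][i] += eps
        am[wrt][i] -= eps
        g[i] = (f(*ap) - f(*am)) / (2 * eps)
    return g


def rel_err(a, b):
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    return np.max(np.abs(a - b) / np.maximum(1e-8, np.abs(a) + np.abs(b)))
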