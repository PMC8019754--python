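import numpy as np
import pytest

from upffs.dfcn import RoiTimeSeries, SlidingWindowSpec, build_lo_dfcn


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def gaussian_ts(rng):
    """M=5, T=80 Gaussian ROI time series from a fixed seed."""
    return RoiTimeSeries("sub-0001", rng.standard_normal((80, 5)), label=0)


@pytest.fixture
def small_lo(gaussian_ts):
    return build_lo_dfcn(gaussian_ts, SlidingWindowSpec(width=20, step=10))


@pytest.fixture
def tensor_stack(rng):
    """Random (n=12, D=3, M=4, M=4) symmetric feature tensors + balanced labels."""
    m, d, n = 4, 3, 12
    x = rng.standard_normal((n, d, m, m))
    x = 0.5 * (x + x.transpose(0, 1, 3, 2))
    for i in range(n):
        for k in range(d):
            np.fill_diagonal(x[i, k], 0.0)
    labels = np.tile([0, 1], n // 2)
    return x, labels
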