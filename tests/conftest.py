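import numpy as np
import pandas as pd
import pytest

from ddprofile.models import Dataset
from ddprofile.sampler import SamplerConfig


@pytest.fixture(scope="session")
def normal_data():
    """n=10 normal sample with known variance 1, recentred so ybar = 0.3."""
    rng = np.random.default_rng(0)
    y = rng.normal(0.3, 1.0, 10)
    y = y - y.mean() + 0.3
    return Dataset("scalar", pd.DataFrame({"y": y}))


@pytest.fixture(scope="session")
def beta_data_50():
    from ddprofile.simulate import gen_beta
    return gen_beta(50, 3.0, 2.0, seed=1)


@pytest.fixture(scope="session")
def fast_cfg():
    """Small sampler settings for conjugate / analytic models."""
    return SamplerConfig(chains=32, draws=150, warmup=600, thin=2, seed=5)


@pytest.fixture(scope="session")
def big_cfg():
    """S = 20,000 settings for curve-accuracy checks on cheap models."""
    return SamplerConfig(chains=40, draws=500, warmup=800, thin=1, seed=11)


def overlap_grid(curve_a, curve_b, frac=0.9, n=81):
    """Uniform grid over the central `frac` of the overlap of two curves."""
    lo = max(curve_a.psi_grid[0], curve_b.psi_grid[0])
    hi = min(curve_a.psi_grid[-1], curve_b.psi_grid[-1])
    pad = 0.5 * (1.0 - frac) * (hi - lo)
    return np.linspace(lo + pad, hi - pad, n)


def max_curve_dev(curve_a, curve_b, frac=0.9):
    """Max abs difference of two normalized curves on their central overlap."""
    g = overlap_grid(curve_a, curve_b, frac)
    va = curve_a.interp(g)
    vb = curve_b.interp(g)
    va = va - va.max()
    vb = vb - vb.max()
    return float(np.max(np.abs(va - vb)))


def central_slice(n, frac=0.9):
    k = int(round(0.5 * (1.0 - frac) * n))
    return slice(k, n - k)
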