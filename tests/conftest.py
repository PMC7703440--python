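import numpy as np
import pytest
from scipy.special import expit

import sdmbias as sb
from sdmbias.envfields import EnvLayer, EnvStack
from sdmbias.grid import morans_i


@pytest.fixture(scope="session")
def ireland_grid():
    return sb.ireland_like_grid()


@pytest.fixture(scope="session")
def default_env(ireland_grid):
    """The calibrated ten-layer default stack (shared; ~1 s to build)."""
    return sb.default_env_stack(ireland_grid, seed=11)


@pytest.fixture(scope="session")
def scaled_run():
    """One desk-scale factorial experiment (shared across slow tests)."""
    return sb.run_experiment(sb.scaled_design(), seed=1)


@pytest.fixture()
def small_grid():
    return sb.build_grid(6, 6, 10.0)


def quick_stack(grid, seed=7, range_km=20.0):
    """Ten named layers without Moran's I calibration — fast stand-in.

    High autocorrelation targets are unreachable on very small extents,
    so unit tests that only need named layers use this instead of the
    calibrated default stack.
    """
    rng = np.random.default_rng(seed)
    layers = []
    for name, _target, kind, transform in sb.DEFAULT_LAYER_SPECS:
        v = sb.gaussian_field(grid, range_km, int(rng.integers(2**31)))
        vals = expit(v) if transform == "logistic" else v
        layers.append(EnvLayer(name=name, values=vals,
                               morans_i=morans_i(vals, grid), kind=kind))
    return EnvStack(grid, layers)


@pytest.fixture()
def quick_env(small_grid):
    return quick_stack(small_grid)


@pytest.fixture()
def small_community(quick_env):
    return sb.generate_community(quick_env, 12, seed=3,
                                 prevalence_floor=0.05, min_occupied=2)
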