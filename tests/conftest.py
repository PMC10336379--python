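import numpy as np
import pytest

from turingmix import Grid, ModelParams, SimConfig


@pytest.fixture
def base_params() -> ModelParams:
    """Canonical parameter set used across the replication figures."""
    return ModelParams(phi0=0.2, chi=0.0, h=5.0, k=0.1, D_A=1.0, D_I=5.0, w=1.0)


@pytest.fixture
def grid_1d() -> Grid:
    return Grid((200,), dx=1.0)


@pytest.fixture
def grid_2d() -> Grid:
    return Grid((64, 64), dx=1.0)


@pytest.fixture
def quick_config() -> SimConfig:
    return SimConfig(t_end=10.0, seed=123, noise_amplitude=1e-3)


def random_simplex_points(rng: np.random.Generator, n: int) -> np.ndarray:
    """n interior points (phiA, phiI) of the open simplex, away from edges."""
    pts = []
    while len(pts) < n:
        a, b = rng.uniform(0.02, 0.96, size=2)
        if a + b < 0.98:
            pts.append((a, b))
    return np.array(pts)


def random_valid_params(rng: np.random.Generator) -> ModelParams:
    return ModelParams(
        phi0=float(rng.uniform(0.05, 0.35)),
        chi=float(rng.uniform(-6.0, 6.0)),
        h=float(rng.uniform(1.0, 10.0)),
        k=float(10 ** rng.uniform(-2, 0)),
        D_A=1.0,
        D_I=float(10 ** rng.uniform(-0.3, 1.3)),
        w=1.0,
    )
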