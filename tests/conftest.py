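import numpy as np
import pytest

from samsce.config import SimulationConfig, desk_scale


def rect_ring(w: float, h: float, nx: int, ny: int) -> np.ndarray:
    """Rectangle [0,w]x[0,h] sampled with nx/ny intervals per edge (CCW)."""
    pts = []
    for k in range(nx):
        pts.append((w * k / nx, 0.0))
    for k in range(ny):
        pts.append((w, h * k / ny))
    for k in range(nx):
        pts.append((w - w * k / nx, h))
    for k in range(ny):
        pts.append((0.0, h - h * k / ny))
    return np.array(pts, dtype=float)


def circle_ring(r: float, n: int, center=(0.0, 0.0), phase=0.0) -> np.ndarray:
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + r * np.cos(ang),
                            center[1] + r * np.sin(ang)])


def blob_ring(rng: np.random.Generator, n: int = 24) -> np.ndarray:
    """Random star-shaped simple polygon: smooth radial perturbation of a circle."""
    base = 1.0 + 0.35 * np.sin(np.linspace(0, 2 * np.pi, n, endpoint=False)
                               * rng.integers(1, 4) + rng.uniform(0, 2 * np.pi))
    base *= rng.uniform(0.8, 2.0)
    base += rng.uniform(-0.05, 0.05, size=n)
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([base * np.cos(ang), base * np.sin(ang)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def desk_config() -> SimulationConfig:
    return desk_scale(mechanism="CAE-E", condition="wildtype", seed=1)
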