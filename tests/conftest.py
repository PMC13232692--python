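import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def square10():
    """Axis-aligned 10x10 mm square with corners on integer coordinates."""
    return np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])


def circle_polygon(radius, center=(0.0, 0.0), n=720):
    phi = 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(phi),
                            center[1] + radius * np.sin(phi)])


def star_polygon(rng, n=400, r_mean=12.0, wobble=0.25, center=(0.0, 0.0)):
    """Random smooth star-shaped polygon (positive radius function of angle)."""
    phi = 2 * np.pi * np.arange(n) / n
    r = np.full(n, r_mean)
    for harmonic in range(1, 5):
        amp = wobble * r_mean / harmonic * rng.uniform(0.2, 1.0)
        r += amp * np.cos(harmonic * phi + rng.uniform(0, 2 * np.pi))
    r = np.maximum(r, 0.2 * r_mean)
    return np.column_stack([center[0] + r * np.cos(phi),
                            center[1] + r * np.sin(phi)])


@pytest.fixture
def circle_factory():
    return circle_polygon


@pytest.fixture
def star_factory():
    return star_polygon
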