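import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from msigrade.core import (FeatureDescriptor, PeakMatrix, PixelGrid, POSITIVE)
from msigrade.synthetic import generate_peak_matrix, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The default 128x128 seeded phantom (shared, read-only)."""
    return generate_phantom(seed=1)


@pytest.fixture(scope="session")
def default_matrix(default_phantom):
    return generate_peak_matrix(default_phantom, seed=1)


@pytest.fixture
def small_matrix():
    """Deterministic 10-pixel, 5-feature matrix."""
    rng = np.random.default_rng(42)
    grid = PixelGrid.full_raster(5, 2)
    feats = [FeatureDescriptor(POSITIVE, 500.0 + 10 * j) for j in range(5)]
    return PeakMatrix(grid, feats, rng.uniform(0.1, 10.0, (10, 5)))
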