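"""Shared fixtures: the three published discovered models and trajectories."""

import numpy as np
import pytest

from cartdyn import CoefficientMatrix, simulate_trajectories

# Discovered models for the three effector-to-target ratios, on the library
# [x, y, x^2, xy, y^2, x^3, x^2y, xy^2, y^3].
XI_HIGH = np.array([   # E:T = 1:4, eight terms
    [0.121, 0.0, 0.061, 0.0, 0.0, -0.018, 0.0, -0.593, 0.0],
    [0.0, 0.191, 0.0, 0.035, -0.351, 0.0, -0.009, 0.0, 0.0],
])
XI_MEDIUM = np.array([  # E:T = 1:8, eight terms
    [0.237, 0.0, 0.04, -0.626, 0.0, -0.012, 0.0, 0.0, 0.0],
    [0.0, 0.112, 0.0, 0.051, -0.358, 0.0, -0.009, 0.0, 0.0],
])
XI_LOW = np.array([     # E:T = 1:20, six terms
    [0.150, 0.0, -0.012, -0.545, 0.0, 0.0, 0.0, 0.0, 0.0],
    [0.0, 0.0, 0.0, -0.002, 0.0, 0.0, 0.005, -0.063, 0.0],
])

PRINTED_MODELS = {
    "1:4": (XI_HIGH, 0.5),
    "1:8": (XI_MEDIUM, 0.5),
    "1:20": (XI_LOW, 0.1),
}


@pytest.fixture(scope="session")
def t_grid():
    """150 h at 15-minute sampling."""
    return np.arange(0.0, 150.0001, 0.25)


@pytest.fixture(scope="session")
def printed_trajectories(t_grid):
    """Noise-free trajectories of the three published models."""
    out = {}
    for label, (xi, y0) in PRINTED_MODELS.items():
        x, y = simulate_trajectories(
            CoefficientMatrix(xi), 2.0, y0, t_grid, rtol=1e-10, atol=1e-12
        )
        out[label] = (x, y)
    return out
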