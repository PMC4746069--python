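import numpy as np
import pytest

from asymmorph import LandmarkSimParams, echinoid_oral_template, simulate_landmarks
from asymmorph.landmark_io import SymmetryMap


@pytest.fixture(scope="session")
def template():
    """Built-in 21-landmark echinoid oral template: (coords, map, names)."""
    return echinoid_oral_template()


@pytest.fixture(scope="session")
def tiny_map():
    """k=2 pairs + u=1 median on a 5-landmark 2D configuration."""
    return SymmetryMap(pairs=((0, 1), (2, 3)), medians=(4,))


@pytest.fixture(scope="session")
def tiny_symmetric_base():
    """Exactly symmetric 5-landmark 2D shape matching ``tiny_map``."""
    return np.array(
        [
            [-1.0, 0.5],
            [1.0, 0.5],
            [-0.6, -0.8],
            [0.6, -0.8],
            [0.0, 1.1],
        ]
    )


@pytest.fixture(scope="session")
def small_sample(template):
    """Small replicated synthetic sample under the default study conditions."""
    _, smap, _ = template
    sample = simulate_landmarks(LandmarkSimParams(n_individuals=8, replicates=2, seed=11))
    return sample, smap


def rotation_2d(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


@pytest.fixture(scope="session")
def rot2d():
    return rotation_2d
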