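import numpy as np
import pytest
from scipy.spatial.transform import Rotation as ScipyRotation


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (independent of the package's code)."""
    return ScipyRotation.random(random_state=int(rng.integers(2**31))).as_matrix()


def random_rigid(rng: np.random.Generator):
    """Random rotation + translation pair for equivariance checks."""
    return random_rotation(rng), rng.uniform(-500.0, 500.0, size=3)


@pytest.fixture
def scapula_template():
    return {
        "glenosphere_center": np.array([0.0, 0.0, 0.0]),
        "trigonum_spinae": np.array([0.0, 0.0, -110.0]),
        "inferior_angle": np.array([0.0, -120.0, -60.0]),
    }
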