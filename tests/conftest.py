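import numpy as np
import pytest

from psm3d import (
    CalibrationMap,
    EchoModel,
    RingPhantom,
    SimConfig,
    build_sector_database,
    simulate_acquisition,
)

CONTACT_RADIUS = 26.0  # ring 20 + tube 2 + reference stand-off 4


@pytest.fixture(scope="session")
def phantom():
    return RingPhantom()


@pytest.fixture(scope="session")
def calibration():
    return CalibrationMap()


@pytest.fixture(scope="session")
def echo_model():
    return EchoModel()


@pytest.fixture(scope="session")
def db8():
    return build_sector_database((0.0, 0.0, 0.0), None, 20.0, 8, 0.3)


@pytest.fixture(scope="session")
def db128():
    return build_sector_database((0.0, 0.0, 0.0), None, 20.0, 128, 0.3)


@pytest.fixture(scope="session")
def noiseless_cfg8():
    return SimConfig(delta_v=8, seed=7, pose_sd=0.0, angle_sd=0.0,
                     pressure_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_frames8(phantom, noiseless_cfg8, calibration, echo_model):
    return simulate_acquisition(phantom, noiseless_cfg8, calibration, echo_model)


def random_noncollinear_triples(rng, n, scale=10.0, min_cross=1e-3):
    """Seeded non-degenerate point triples for duality properties."""
    out = []
    while len(out) < n:
        a, b, c = rng.uniform(-scale, scale, (3, 3))
        if np.linalg.norm(np.cross(b - a, c - a)) > min_cross:
            out.append((a, b, c))
    return out
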