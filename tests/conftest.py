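import numpy as np
import pytest

from protofil.synthetic import make_interface_pair, make_toy_protomer


@pytest.fixture(scope="session")
def toy_protomer():
    return make_toy_protomer(seed=42)


@pytest.fixture(scope="session")
def ccdc61_like_fixture():
    """Three-chain interface pair with the CCDC61 filament geometry:
    C2 axes at 60 deg with -40 A common-perpendicular offset, so the
    composed generator is a 120 deg screw with -80 A rise (left-handed)."""
    return make_interface_pair(60.0, -40.0, seed=7)


@pytest.fixture(scope="session")
def sas6_ring_fixture():
    """Interface pair whose composed generator is a pure 40 deg rotation:
    the 9-fold SAS6 ring geometry."""
    return make_interface_pair(20.0, 0.0, seed=7)


def random_rigid_transform(rng):
    """Uniform random proper rigid transform with angle in (1, 180] deg."""
    from scipy.spatial.transform import Rotation

    from protofil.rigid import RigidTransform

    while True:
        q = rng.normal(size=4)
        rot = Rotation.from_quat(q / np.linalg.norm(q))
        angle = np.rad2deg(np.linalg.norm(rot.as_rotvec()))
        if 1.0 < angle <= 180.0:
            break
    t = rng.uniform(-50, 50, size=3)
    return RigidTransform(rot.as_matrix(), t)
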