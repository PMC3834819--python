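import numpy as np
import pytest

from zlattice import (
    Arrangement,
    DummyDomainSpec,
    HelixFrame,
    build_ideal_zdna,
    dummy_pose_rule,
    make_fixture_complex,
    pair_duplex,
)


@pytest.fixture(scope="session")
def cg6_duplex():
    """Ideal 12 bp (GC)x6 duplex + frame (reference strand starts with G so
    reference-strand guanosines sit at even bp indices)."""
    return build_ideal_zdna("GCGCGCGCGCGC")


@pytest.fixture(scope="session")
def cg6_map(cg6_duplex):
    st, _ = cg6_duplex
    return pair_duplex(st)


@pytest.fixture(scope="session")
def default_frame():
    return HelixFrame()


@pytest.fixture(scope="session")
def small_domain_rule(default_frame):
    """Pose rule for a compact radius-5 dummy domain (never clashes)."""
    return dummy_pose_rule(DummyDomainSpec(n_atoms=60, radii=(5.0,), seed=11),
                           frame=default_frame)


@pytest.fixture(scope="session")
def realistic_domain_rule(default_frame):
    """Pose rule for the default ~65-residue-sized dummy domain."""
    return dummy_pose_rule(DummyDomainSpec(seed=11), frame=default_frame)


@pytest.fixture(scope="session")
def fixture_6p3():
    """Planted-truth (6 + 3) complex on 12 bp with radius-5 domains."""
    return make_fixture_complex(
        Arrangement(6, 3), DummyDomainSpec(n_atoms=60, radii=(5.0,), seed=7),
        helix_length_bp=12,
    )


def random_rigid(rng):
    from scipy.spatial.transform import Rotation

    from zlattice import RigidTransform

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1)))
    return RigidTransform(R.as_matrix(), rng.uniform(-30, 30, 3))
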