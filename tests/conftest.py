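import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tube_phantom():
    from vasculate.fixtures import PhantomSpec, make_tube_phantom

    return make_tube_phantom(PhantomSpec(kind="tube", length=40, radius=3))


@pytest.fixture(scope="session")
def y_phantom():
    from vasculate.fixtures import PhantomSpec, make_tube_phantom

    return make_tube_phantom(PhantomSpec(kind="Y", length=40, radius=3))


@pytest.fixture(scope="session")
def noisy_helix():
    """Quantization-noise helix samples plus the analytic curvature."""
    from vasculate.fixtures import helix_points, make_noisy_centerline

    pts, kappa = helix_points(n=127, radius=10.0, pitch=5.0, turns=2.0)
    noisy = make_noisy_centerline(pts, amplitude=0.5, seed=1)
    return noisy, pts, kappa


def straight_segment(p0, p1, radius, dl=2.0, arterial_index=0):
    from vasculate.fixtures import _straight_segment

    return _straight_segment(p0, p1, radius, dl=dl,
                             arterial_index=arterial_index)
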