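"""Shared fixtures: synthetic contours and relaxed model states.

Expensive relaxations are session-scoped so several tests can share them;
all randomness is seeded through FixtureSpec.
"""

import numpy as np
import pytest

import blebsim as bs


@pytest.fixture(scope="session")
def params():
    return bs.ModelParams.default()


@pytest.fixture(scope="session")
def circle_spec():
    return bs.FixtureSpec(shape="circle", radius=5.0)


@pytest.fixture(scope="session")
def circle_contour(circle_spec):
    return bs.make_contour(circle_spec)


@pytest.fixture(scope="session")
def notched_spec():
    return bs.FixtureSpec(shape="notched_circle", radius=5.0,
                          notches=((90.0, 1.0, 25.0),))


@pytest.fixture(scope="session")
def notched_contour(notched_spec):
    return bs.make_contour(notched_spec)


@pytest.fixture(scope="session")
def circle_subcritical(circle_contour, params):
    """(p_sub, relaxed state) for the homogeneous circle."""
    return bs.find_subcritical_pressure(circle_contour, params, return_state=True)


@pytest.fixture(scope="session")
def notched_subcritical(notched_contour, params):
    """(p_sub, relaxed state) for the single-notch circle."""
    return bs.find_subcritical_pressure(notched_contour, params, return_state=True)


@pytest.fixture(scope="session")
def notch_center_node(notched_contour):
    """Node of minimum signed curvature (the notch centre)."""
    return int(np.argmin(bs.signed_curvature(notched_contour)))


def cyclic_node_distance(i: int, j: int, n: int) -> int:
    return min(abs(i - j), n - abs(i - j))


@pytest.fixture(scope="session")
def node_distance():
    return cyclic_node_distance
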