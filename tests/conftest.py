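import numpy as np
import pytest

from ccmorph.curves import Curve
from ccmorph.synthetic_data import CrescentParams, make_crescent


@pytest.fixture
def unit_square_cw():
    # clockwise under the image convention (y down): positive shoelace sum
    return Curve(points=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def unit_square_ccw():
    return Curve(points=np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]]))


def circle_curve(radius=20.0, n=60, center=(64.0, 64.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Curve(points=np.column_stack([center[0] + radius * np.cos(th),
                                         center[1] + radius * np.sin(th)]))


def ellipse_curve(a=24.0, b=16.0, n=60, center=(64.0, 64.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Curve(points=np.column_stack([center[0] + a * np.cos(th),
                                         center[1] + b * np.sin(th)]))


@pytest.fixture
def circle60():
    return circle_curve()


@pytest.fixture
def ellipse60():
    return ellipse_curve()


@pytest.fixture
def crescent60():
    return make_crescent(CrescentParams(n_points=60))


@pytest.fixture
def crescent200():
    return make_crescent(CrescentParams())
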