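import numpy as np
import pytest

from spinetape.tape import ArcElement, SpinalCurve


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def straight_tape():
    """29 collinear 30 mm line elements along +x (the native tape layout)."""
    return [
        ArcElement((30.0 * i, 0.0), (30.0 * i + 15.0, 0.0), (30.0 * (i + 1), 0.0), i)
        for i in range(29)
    ]


@pytest.fixture
def circle_curve():
    """A 200 mm diameter circle as an open curve (cut at angle 0)."""
    theta = np.linspace(0.0, 2 * np.pi, 4001)
    pts = 100.0 * np.column_stack([np.cos(theta), np.sin(theta)])
    return SpinalCurve.from_points(pts)


@pytest.fixture
def sine_curve():
    """A gentle smooth test curve: low-amplitude sine over 870 mm."""
    x = np.linspace(0.0, 870.0, 4001)
    y = 40.0 * np.sin(2 * np.pi * x / 870.0)
    return SpinalCurve.from_points(np.column_stack([x, y]))
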