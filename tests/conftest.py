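import numpy as np
import pytest

from mfepath import fixtures as fx
from mfepath.path_model import interpolate_linear


@pytest.fixture(scope="session")
def ala_scenario():
    """The 2-D curved-valley study scenario (surface + refined minima)."""
    return fx.ala_like_2d()


@pytest.fixture(scope="session")
def straight_path_40(ala_scenario):
    return interpolate_linear(ala_scenario.reactant, ala_scenario.product,
                              40, space=ala_scenario.space)


def point_to_polyline(points: np.ndarray, poly: np.ndarray) -> float:
    """Max over points of the point-to-segment distance to a dense polyline."""
    a, b = poly[:-1], poly[1:]
    ab = b - a
    denom = np.sum(ab * ab, axis=1)
    worst = 0.0
    for p in np.atleast_2d(points):
        ap = p[None, :] - a
        t = np.clip(np.sum(ap * ab, axis=1) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        worst = max(worst, float(np.min(np.linalg.norm(p[None, :] - proj, axis=1))))
    return worst
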