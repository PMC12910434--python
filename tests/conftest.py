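import numpy as np
import pytest

from nucleodrop.mesh import TriSurface


@pytest.fixture(scope="session")
def unit_cube():
    """Closed, outward-oriented 12-triangle unit cube."""
    v = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (-z)
            [4, 5, 6], [4, 6, 7],  # top (+z)
            [0, 1, 5], [0, 5, 4],  # front (-y)
            [1, 2, 6], [1, 6, 5],  # right (+x)
            [2, 3, 7], [2, 7, 6],  # back (+y)
            [3, 0, 4], [3, 4, 7],  # left (-x)
        ]
    )
    return TriSurface(v, f)


@pytest.fixture(scope="session")
def fine_sphere():
    """Unit sphere at ~2900 faces (shared by convergence tests)."""
    from nucleodrop.mesh import make_initial_mesh

    return make_initial_mesh({"kind": "sphere", "radius": 1.0}, 0.1, seed=1)


def star_contour_points(R=10.0, eps=0.2, k=5, n=4000):
    """r(theta) = R (1 + eps cos k theta), resampled uniformly in arc
    length (used by several EFC tests)."""
    th = np.linspace(0, 2 * np.pi, 200001)
    r = R * (1 + eps * np.cos(k * th))
    x, y = r * np.cos(th), r * np.sin(th)
    s = np.concatenate([[0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
    u = np.linspace(0, s[-1], n, endpoint=False)
    return np.column_stack([np.interp(u, s, x), np.interp(u, s, y)])
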