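import numpy as np
import pytest

from cleanv import (
    SurfaceGeometry,
    geodesic_distances,
    load_mesh,
    make_synthetic_mesh,
)


@pytest.fixture(scope="session")
def grid10():
    """10x10 planar triangulated lattice (V=100), distances computed."""
    return make_synthetic_mesh("grid", 10)


@pytest.fixture(scope="session")
def grid5():
    return make_synthetic_mesh("grid", 5)


@pytest.fixture()
def line3():
    """Three collinear vertices at x = 0, 1, 3 (edge lengths 1 and 2)."""
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]])
    faces = np.array([[0, 1, 1], [1, 2, 2]])  # degenerate faces as an edge list
    return geodesic_distances(load_mesh(coords, faces))


@pytest.fixture()
def tetrahedron():
    coords = np.array(
        [[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0], [0.0, 0, 1]]
    )
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return coords, faces


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_quadratic_form(d: np.ndarray, K: np.ndarray) -> float:
    """Independent double-loop oracle for d' K d."""
    total = 0.0
    n = d.size
    for i in range(n):
        for j in range(n):
            total += d[i] * K[i, j] * d[j]
    return total


def floyd_warshall_oracle(coords, faces, mask=None):
    """Independent all-pairs shortest path on the mesh edge graph."""
    V = coords.shape[0]
    if mask is None:
        mask = np.ones(V, dtype=bool)
    D = np.full((V, V), np.inf)
    np.fill_diagonal(D, 0.0)
    for tri in faces:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            i, j = tri[a], tri[b]
            if mask[i] and mask[j]:
                w = float(np.linalg.norm(coords[i] - coords[j]))
                D[i, j] = min(D[i, j], w)
                D[j, i] = min(D[j, i], w)
    for k in range(V):
        if not mask[k]:
            continue
        D = np.minimum(D, D[:, k][:, None] + D[k, :][None, :])
    D[~mask, :] = np.inf
    D[:, ~mask] = np.inf
    np.fill_diagonal(D, 0.0)
    return D
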