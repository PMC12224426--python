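"""Generative simulator for calibration, power and reproducibility studies.

Draws data from the same hierarchical model the test targets: at vertex v,

    y(v) = X beta(v) + r(v) + b(v) + delta(v),
    r(v) ~ N(0, theta2(v) * K_gen),      independently across vertices,
    b_i  ~ N(0, sigma2 * Phi(phi, D)),   independently across images,
    delta_i ~ N(0, tau2 * I).

``K_gen`` encodes which images truly covary; it may differ from the kernel
the analysis assumes (e.g. a null scenario claims 20 test-retest pairs in
the design while generating fully independent images, and a partial-signal
scenario makes only a fraction of the claimed pairs real). Scenario
builders mirror the standard study sizes for such designs: 20 subject pairs
(N = 40 images) for test-retest and 60 twin pairs (N = 120 images) for
heritability, with the signal confined to a contiguous geodesic patch
covering roughly 10% of the surface so that cluster enhancement is
exercised the way contiguous cortical signal would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import RelatednessMatrix, kinship_test_retest, kinship_twins
from .mesh import SurfaceGeometry, geodesic_distances, load_mesh
from .spatial import exponential_sacf

#: SACF target used when phi is derived from the mesh scale: correlation
#: at the median pairwise geodesic distance.
DEFAULT_MEDIAN_CORRELATION = 0.3
#: fraction of vertices inside the default signal patch
DEFAULT_SIGNAL_FRACTION = 0.10
#: default signal strength: theta2 equal to the white-noise variance,
#: i.e. a vertex-level intraclass correlation of 0.5 inside the patch
DEFAULT_THETA2 = 1.0
DEFAULT_SIGMA2 = 1.0
DEFAULT_TAU2 = 1.0


@dataclass
class SimulationScenario:
    """A fully specified generative setting.

    K is the kernel the analysis will assume; K_gen (default: same) is the
    kernel actually used to generate between-image dependence. theta2_map
    is per-vertex and identically zero in null scenarios.
    """

    geometry: SurfaceGeometry
    K: RelatednessMatrix
    theta2_map: np.ndarray
    sigma2: float = DEFAULT_SIGMA2
    tau2: float = DEFAULT_TAU2
    phi: float | None = None
    X: np.ndarray | None = None
    beta_map: np.ndarray | None = None
    K_gen: RelatednessMatrix | None = None
    design: "np.ndarray | None" = None  # per-image design labels (subject/pair ids)
    zygosity: np.ndarray | None = None
    mode: str = "custom"

    def __post_init__(self):
        self.theta2_map = np.asarray(self.theta2_map, dtype=float)
        if np.any(self.theta2_map < 0):
            raise ValueError("theta2_map must be nonnegative")
        if self.theta2_map.shape != (self.geometry.n_vertices,):
            raise ValueError("theta2_map length must equal the vertex count")
        if self.phi is None:
            self.phi = phi_for_median_correlation(self.geometry.D)

    @property
    def n_images(self) -> int:
        return self.K.n_images

    @property
    def is_null(self) -> bool:
        gen = self.K_gen if self.K_gen is not None else self.K
        return not np.any(self.theta2_map) or not gen.has_related_pairs()


def make_synthetic_mesh(kind: str = "grid", size: int = 10) -> SurfaceGeometry:
    """Built-in meshes with geodesic distances precomputed.

    kind='grid': planar size x size triangulated lattice, unit (1 mm)
    spacing, 2*(size-1)^2 triangles. kind='sphere': icosphere with ``size``
    subdivisions, radius 50 mm (a cortical-hemisphere scale).
    """
    if kind == "grid" and size < 2:
        raise ValueError("grid size must be >= 2")
    if kind == "sphere" and size < 0:
        raise ValueError("sphere subdivisions must be >= 0")
    if kind == "grid":
        ii, jj = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        coords = np.column_stack(
            [ii.ravel().astype(float), jj.ravel().astype(float), np.zeros(size * size)]
        )
        faces = []
        for i in range(size - 1):
            for j in range(size - 1):
                a = i * size + j
                b = a + 1
                c = a + size
                d = c + 1
                faces.append([a, b, c])
                faces.append([b, d, c])
        faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    elif kind == "sphere":
        import trimesh

        tm = trimesh.creation.icosphere(subdivisions=size, radius=50.0)
        coords = np.asarray(tm.vertices, dtype=float)
        faces = np.asarray(tm.faces, dtype=np.int64)
    else:
        raise ValueError(f"unknown mesh kind {kind!r}")
    geom = load_mesh(coords, faces)
    return geodesic_distances(geom)


def phi_for_median_correlation(
    D: np.ndarray, target: float = DEFAULT_MEDIAN_CORRELATION
) -> float:
    """Decay rate giving SACF ``target`` at the median pairwise distance."""
    off = np.asarray(D, dtype=float).copy()
    np.fill_diagonal(off, np.nan)
    finite = off[np.isfinite(off) & (off > 0)]
    return float(-np.log(target) / np.median(finite))


def signal_patch(geometry: SurfaceGeometry, fraction: float, center: int | None = None) -> np.ndarray:
    """Vertex indices of a geodesic disc covering ~``fraction`` of vertices.

    The disc grows around ``center`` (default: the active vertex closest to
    the centroid) until the requested vertex count is reached.
    """
    active = geometry.active
    if center is None:
        centroid = geometry.coords[active].mean(axis=0)
        center = active[
            int(np.argmin(np.linalg.norm(geometry.coords[active] - centroid, axis=1)))
        ]
    n_target = max(1, int(round(fraction * active.size)))
    dists = geometry.D[center, active]
    order = np.argsort(dists, kind="stable")
    return np.sort(active[order[:n_target]])


def _psd_factor(K: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix via eigendecomposition (K may be singular)."""
    vals, vecs = np.linalg.eigh(K)
    if vals.min() < -1e-8 * max(1.0, vals.max()):
        raise ValueError(
            f"generation kernel is not PSD (smallest eigenvalue {vals.min():.3g})"
        )
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_dataset(scenario: SimulationScenario, seed: int = 0):
    """Draw (Y, X, K) from the scenario's generative model, seeded.

    Returns the N x V data matrix, the covariate matrix (intercept-only when
    the scenario specifies none) and the analysis kernel.
    """
    rng = np.random.default_rng(seed)
    geom = scenario.geometry
    N = scenario.n_images
    V = geom.n_vertices
    active = geom.active

    Kgen = (scenario.K_gen if scenario.K_gen is not None else scenario.K).K
    Lk = _psd_factor(Kgen)

    Y = np.zeros((N, V))
    # between-image component r(v): independent across vertices
    hot = np.flatnonzero(scenario.theta2_map > 0)
    if hot.size:
        Z = rng.standard_normal((N, hot.size))
        Y[:, hot] += (Lk @ Z) * np.sqrt(scenario.theta2_map[hot])

    # within-image spatial component b_i on the active vertices
    if scenario.sigma2 > 0:
        D_act = geom.D[np.ix_(active, active)]
        Phi = exponential_sacf(D_act, scenario.phi)
        Lphi = np.linalg.cholesky(
            scenario.sigma2 * Phi + 1e-10 * np.eye(active.size)
        )
        Y[:, active] += rng.standard_normal((N, active.size)) @ Lphi.T

    # white noise
    if scenario.tau2 > 0:
        Y += np.sqrt(scenario.tau2) * rng.standard_normal((N, V))

    X = scenario.X if scenario.X is not None else np.ones((N, 1))
    if scenario.beta_map is not None:
        Y += np.asarray(X, dtype=float) @ np.atleast_2d(scenario.beta_map)
    return Y, np.asarray(X, dtype=float), scenario.K


def hcp_style_scenarios(
    mode: str,
    geometry: SurfaceGeometry,
    *,
    n_units: int | None = None,
    prop_true: float = 1.0,
    theta2: float = DEFAULT_THETA2,
    sigma2: float = DEFAULT_SIGMA2,
    tau2: float = DEFAULT_TAU2,
    phi: float | None = None,
    signal_fraction: float = DEFAULT_SIGNAL_FRACTION,
) -> SimulationScenario:
    """Scenario builders mirroring the standard study structures.

    mode='null': the analysis kernel claims pseudo test-retest pairs but the
    generated images are fully independent (theta2 identically zero), so any
    rejection is a family-wise false positive.
    mode='test_retest': n_units subject pairs (default 20, N = 40 images);
    a proportion ``prop_true`` of the pairs are real (share the r component
    inside the signal patch), the rest are pseudo pairs.
    mode='twin': n_units twin pairs (default 60, N = 120 images), half MZ /
    half DZ, same partial-truth mechanism.
    """
    if not 0.0 <= prop_true <= 1.0:
        raise ValueError("prop_true must be in [0, 1]")
    V = geometry.n_vertices

    if mode == "null":
        n_units = 20 if n_units is None else n_units
        subjects = np.repeat(np.arange(n_units), 2)
        K = kinship_test_retest(subjects)
        K_gen = RelatednessMatrix(K=np.eye(2 * n_units), design_label="test_retest")
        theta2_map = np.zeros(V)
        scen = SimulationScenario(
            geometry=geometry,
            K=K,
            theta2_map=theta2_map,
            sigma2=sigma2,
            tau2=tau2,
            phi=phi,
            K_gen=K_gen,
            design=subjects,
            mode=mode,
        )
        return scen

    if mode == "test_retest":
        n_units = 20 if n_units is None else n_units
        subjects = np.repeat(np.arange(n_units), 2)
        K = kinship_test_retest(subjects)
        n_true = int(round(prop_true * n_units))
        K_gen_mat = np.eye(2 * n_units)
        for s in range(n_true):
            i, j = 2 * s, 2 * s + 1
            K_gen_mat[i, j] = K_gen_mat[j, i] = 1.0
        K_gen = RelatednessMatrix(K=K_gen_mat, design_label="test_retest")
        design = subjects
        zyg = None
    elif mode == "twin":
        n_units = 60 if n_units is None else n_units
        pairs = np.repeat(np.arange(n_units), 2)
        n_mz = n_units // 2
        zyg = np.repeat(
            np.array(["MZ"] * n_mz + ["DZ"] * (n_units - n_mz)), 2
        )
        K = kinship_twins(pairs, zyg)
        n_true = int(round(prop_true * n_units))
        K_gen_mat = np.eye(2 * n_units)
        for s in range(n_true):
            i, j = 2 * s, 2 * s + 1
            coef = 1.0 if zyg[i] == "MZ" else 0.5
            K_gen_mat[i, j] = K_gen_mat[j, i] = coef
        K_gen = RelatednessMatrix(K=K_gen_mat, design_label="twin")
        design = pairs
    else:
        raise ValueError(f"unknown mode {mode!r}")

    theta2_map = np.zeros(V)
    if theta2 > 0 and prop_true > 0:
        patch = signal_patch(geometry, signal_fraction)
        theta2_map[patch] = theta2
    return SimulationScenario(
        geometry=geometry,
        K=K,
        theta2_map=theta2_map,
        sigma2=sigma2,
        tau2=tau2,
        phi=phi,
        K_gen=K_gen,
        design=design,
        zygosity=zyg,
        mode=mode,
    )
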