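"""Within-image spatial noise model: Sigma = sigma2 * Phi(phi, D) + tau2 * I.

Each residual image is decomposed into a spatially autocorrelated component
``b_i`` with exponential spatial autocorrelation function (SACF)
``Phi[v, v*] = exp(-phi * d(v, v*))`` and white noise ``delta_i`` with
variance ``tau2``. The three parameters are estimated once under the null
by covariance regression: the empirical second-moment matrix of the OLS
residuals is matched to ``sigma2 * Phi + tau2 * I`` in Frobenius norm over
a grid of candidate decay rates ``phi``. Given the fit, the spatial
component is removed by its best linear unbiased predictor (BLUP)
``bhat_i = sigma2 * Phi @ Sigma^{-1} @ eps_i``, leaving spatially whitened
residuals ``delta_i = eps_i - bhat_i`` that feed the score test.

For large meshes the dense solve with ``Sigma^{-1}`` is replaced by a
nearest-neighbor Gaussian process (Vecchia) sparse approximation of the
precision matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

#: mesh size above which the BLUP switches to the NNGP precision by default
EXACT_THRESHOLD = 2000
#: default NNGP conditioning-set size
NNGP_M = 50


@dataclass
class SpatialNoiseParams:
    """Fitted parameters of the within-image noise covariance.

    sigma2 : spatial variance (>= 0)
    tau2 : white-noise variance (> 0)
    phi : SACF decay rate (1/mm); correlation at distance d is exp(-phi*d)
    phi_grid : candidate decay rates searched during fitting
    objective : Frobenius objective value at the optimum (per-image scale)
    """

    sigma2: float
    tau2: float
    phi: float
    phi_grid: np.ndarray = field(default_factory=lambda: np.empty(0))
    objective: float = np.nan


@dataclass
class ResidualImages:
    """Per-image residuals and their spatial/white decomposition.

    E : N x V OLS residuals (rows are images)
    Bhat : N x V BLUP of the spatial component, or None before blup_spatial
    Delta : N x V whitened residuals E - Bhat, or None before blup_spatial
    """

    E: np.ndarray
    Bhat: np.ndarray | None = None
    Delta: np.ndarray | None = None


def exponential_sacf(D: np.ndarray, phi: float) -> np.ndarray:
    """Exponential correlation matrix ``exp(-phi * D)``.

    Entries at infinite distance (masked or disconnected pairs) become 0;
    the diagonal is exactly 1.
    """
    if phi <= 0:
        raise ValueError(f"phi must be positive, got {phi}")
    with np.errstate(over="ignore"):
        Phi = np.exp(-phi * np.asarray(D, dtype=float))
    return Phi


def ols_residuals(Y: np.ndarray, X: np.ndarray) -> ResidualImages:
    """Residualize every vertex on the nuisance covariates at once.

    Computes ``E = (I - X (X'X)^{-1} X') Y`` with a single shared projector,
    identical to running ordinary least squares per vertex.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    N, p = X.shape
    if Y.shape[0] != N:
        raise ValueError(f"Y has {Y.shape[0]} rows but X has {N}")
    if N <= p:
        raise ValueError(f"need more images ({N}) than covariates ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the redundant columns for the error message
        q, r = np.linalg.qr(X)
        redundant = np.flatnonzero(np.abs(np.diag(r)) < 1e-10 * np.abs(r).max())
        raise ValueError(
            f"covariate matrix is rank deficient (rank {rank} < {p}); "
            f"redundant columns: {redundant.tolist()}"
        )
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    E = Y - X @ beta
    return ResidualImages(E=E)


def _nnls_2x2(g11: float, g12: float, g22: float, b1: float, b2: float):
    """Nonnegative least squares for the 2-parameter Gram system.

    Minimizes ||M - s*Phi - t*I||_F^2 over s, t >= 0 given the Gram entries
    g11=<Phi,Phi>, g12=<Phi,I>, g22=<I,I> and right-hand sides b1=<M,Phi>,
    b2=<M,I>. Active-set enumeration over the three feasible candidates.
    """
    det = g11 * g22 - g12 * g12
    candidates = []
    if det > 0:
        s = (b1 * g22 - b2 * g12) / det
        t = (b2 * g11 - b1 * g12) / det
        if s >= 0 and t >= 0:
            candidates.append((s, t))
    # boundary s = 0
    t0 = max(b2 / g22, 0.0)
    candidates.append((0.0, t0))
    # boundary t = 0
    s0 = max(b1 / g11, 0.0) if g11 > 0 else 0.0
    candidates.append((s0, 0.0))

    def obj(st):
        s, t = st
        return s * s * g11 + 2 * s * t * g12 + t * t * g22 - 2 * (s * b1 + t * b2)

    return min(candidates, key=obj)


def default_phi_grid(D: np.ndarray, n: int = 20) -> np.ndarray:
    """Log-spaced decay rates spanning strong to negligible autocorrelation.

    Chosen so the SACF at the median finite pairwise distance ranges from
    0.95 down to 0.01.
    """
    off = np.asarray(D, dtype=float).copy()
    np.fill_diagonal(off, np.nan)
    finite = off[np.isfinite(off) & (off > 0)]
    if finite.size == 0:
        raise ValueError("distance matrix has no positive finite entries")
    dmed = float(np.median(finite))
    lo = -np.log(0.95) / dmed
    hi = -np.log(0.01) / dmed
    return np.geomspace(lo, hi, n)


def fit_covariance_regression(
    E: np.ndarray, D: np.ndarray, phi_grid=None
) -> SpatialNoiseParams:
    """Method-of-moments fit of (sigma2, tau2, phi) by covariance regression.

    Minimizes ``sum_i || eps_i eps_i' - sigma2*Phi(phi,D) - tau2*I ||_F^2``,
    which is equivalent (up to a constant) to fitting the mean outer product
    ``M = (1/N) sum_i eps_i eps_i'``. For each candidate ``phi`` the optimal
    nonnegative (sigma2, tau2) solve a 2 x 2 Gram system in closed form; the
    grid point with the lowest objective wins. ``tau2`` is floored at
    ``1e-8 * var(E)`` so the fitted covariance stays positive definite.
    """
    E = np.asarray(E, dtype=float)
    N, V = E.shape
    if N < 2:
        raise ValueError("need at least 2 images to fit the noise covariance")
    if not np.any(E):
        raise ValueError("residuals are identically zero: no noise to model")
    if phi_grid is None:
        phi_grid = default_phi_grid(D)
    phi_grid = np.asarray(phi_grid, dtype=float)
    if phi_grid.size == 0 or np.any(phi_grid <= 0):
        raise ValueError("phi_grid must be nonempty and positive")

    M = (E.T @ E) / N  # mean outer product of residual images
    trM = float(np.trace(M))
    normM2 = float(np.sum(M * M))
    g22 = float(V)

    best = None
    for phi in phi_grid:
        Phi = exponential_sacf(D, phi)
        g11 = float(np.sum(Phi * Phi))
        g12 = float(np.trace(Phi))  # <Phi, I>
        b1 = float(np.sum(M * Phi))
        s, t = _nnls_2x2(g11, g12, g22, b1, trM)
        obj = (
            normM2
            + s * s * g11
            + 2 * s * t * g12
            + t * t * g22
            - 2 * (s * b1 + t * trM)
        )
        if best is None or obj < best[0]:
            best = (obj, float(s), float(t), float(phi))

    obj, sigma2, tau2, phi = best
    floor = 1e-8 * float(np.var(E))
    tau2 = max(tau2, floor)
    return SpatialNoiseParams(
        sigma2=sigma2, tau2=tau2, phi=phi, phi_grid=phi_grid, objective=obj
    )


def covariance_objective(
    E: np.ndarray, D: np.ndarray, sigma2: float, tau2: float, phi: float
) -> float:
    """Frobenius covariance-regression objective at given parameters."""
    E = np.asarray(E, dtype=float)
    N = E.shape[0]
    M = (E.T @ E) / N
    R = M - sigma2 * exponential_sacf(D, phi) - tau2 * np.eye(E.shape[1])
    return float(np.sum(R * R))


def _nngp_factor(Sigma_fn, D: np.ndarray, order: np.ndarray, m: int):
    """Vecchia sparse factorization of the precision in a given ordering.

    Returns (B, Finv) with Sigma^{-1} approx (I - B)' diag(Finv) (I - B) in
    the *ordered* index space. Row j of B holds the regression coefficients
    of vertex j on its m nearest previously-ordered neighbors.
    """
    V = order.size
    D_ord = D[np.ix_(order, order)]
    rows, cols, vals = [], [], []
    Finv = np.empty(V)
    for j in range(V):
        if j == 0:
            Finv[0] = 1.0 / Sigma_fn(np.zeros((1, 1)))[0, 0]
            continue
        prev = np.arange(j)
        if j > m:
            nearest = np.argpartition(D_ord[j, :j], m)[:m]
            prev = np.sort(nearest)
        d_nn = D_ord[np.ix_(prev, prev)]
        C_nn = Sigma_fn(d_nn)
        c_jn = Sigma_fn(D_ord[j, prev][None, :])[0]
        coef = np.linalg.solve(C_nn, c_jn)
        f = Sigma_fn(np.zeros((1, 1)))[0, 0] - c_jn @ coef
        rows.extend([j] * prev.size)
        cols.extend(prev.tolist())
        vals.extend(coef.tolist())
        Finv[j] = 1.0 / f
    B = sparse.csr_matrix((vals, (rows, cols)), shape=(V, V))
    return B, Finv


def apply_precision(
    params: SpatialNoiseParams,
    D: np.ndarray,
    vectors: np.ndarray,
    method: str = "exact",
    m: int = NNGP_M,
) -> np.ndarray:
    """Apply ``Sigma^{-1}`` to one or more vectors.

    ``vectors`` has shape (V,) or (V, k) with vectors in columns. With
    ``method='exact'`` the dense Cholesky solve is used; with
    ``method='nngp'`` the nearest-neighbor Gaussian process precision with
    ``m`` conditioning neighbors per vertex (ordered by the first spatial
    axis of ``D``'s index, i.e. plain index order here) approximates the
    solve in O(V m^3).
    """
    x = np.asarray(vectors, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    V = x.shape[0]
    if D.shape != (V, V):
        raise ValueError(f"D must be {V} x {V}, got {D.shape}")

    if params.sigma2 == 0:
        out = x / params.tau2
        return out[:, 0] if squeeze else out

    if method == "nngp" and m >= V:
        warnings.warn(
            f"nngp neighbor count m={m} >= V={V}; falling back to exact solve",
            stacklevel=2,
        )
        method = "exact"

    if method == "exact":
        Sigma = params.sigma2 * exponential_sacf(D, params.phi) + params.tau2 * np.eye(V)
        c, low = cho_factor(Sigma)
        out = cho_solve((c, low), x)
    elif method == "nngp":
        def Sigma_fn(d):
            d = np.asarray(d, dtype=float)
            S = params.sigma2 * np.exp(-params.phi * d)
            if d.ndim == 2 and d.shape[0] == d.shape[1]:
                S = S + params.tau2 * np.eye(d.shape[0]) * (d.diagonal() == 0)
            else:
                S = S + params.tau2 * (d == 0)
            return S

        order = np.arange(V)  # caller is expected to pass coordinate-sorted data
        B, Finv = _nngp_factor(Sigma_fn, D, order, m)
        I_minus_B = sparse.eye(V, format="csr") - B
        out = I_minus_B.T @ (Finv[:, None] * (I_minus_B @ x))
        out = np.asarray(out)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out[:, 0] if squeeze else out


def blup_spatial(
    resid: ResidualImages,
    params: SpatialNoiseParams,
    D: np.ndarray,
    *,
    coords: np.ndarray | None = None,
    exact_threshold: int = EXACT_THRESHOLD,
    m: int = NNGP_M,
) -> ResidualImages:
    """Fill ``Bhat`` and ``Delta`` with the spatial BLUP decomposition.

    ``bhat_i = sigma2 * Phi @ Sigma^{-1} @ eps_i`` per image (the conditional
    mean of the spatial component under the fitted joint Gaussian);
    ``Delta = E - Bhat``. The precision is applied densely for
    V <= ``exact_threshold`` and through the NNGP approximation above that,
    with vertices ordered by their first spatial coordinate when ``coords``
    is available.
    """
    E = resid.E
    V = E.shape[1]
    if params.sigma2 == 0:
        resid.Bhat = np.zeros_like(E)
        resid.Delta = E.copy()
        return resid
    if params.tau2 <= 0:
        raise ValueError("fitted covariance is singular (tau2 <= 0)")

    if V <= exact_threshold:
        W = apply_precision(params, D, E.T, method="exact")  # V x N
    else:
        if coords is not None:
            order = np.argsort(coords[:, 0], kind="stable")
        else:
            order = np.arange(V)
        inv = np.empty_like(order)
        inv[order] = np.arange(V)
        D_ord = D[np.ix_(order, order)]
        W_ord = apply_precision(params, D_ord, E.T[order], method="nngp", m=m)
        W = W_ord[inv]
    Phi = exponential_sacf(D, params.phi)
    resid.Bhat = (params.sigma2 * (Phi @ W)).T
    resid.Delta = E - resid.Bhat
    return resid
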