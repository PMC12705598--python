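"""Sparse precision builders for the latent Gaussian Markov random fields.

A Matérn field (smoothness nu = 1 in two dimensions) is represented as the
finite-element solution of the SPDE (kappa^2 - Delta)^(alpha/2) tau x(s) = W(s)
with alpha = 2, giving the sparse precision

    Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G)

with mass-lumped C.  The parameterization follows the convention that fixes
the printed calibration "spatial correlation approximately drops to 0.13 at
the range":  kappa = sqrt(8 nu) / range  and  tau^2 = 1 / (4 pi kappa^2 sigma^2),
so sigma is the marginal standard deviation away from the boundary.

Temporal dependence is first-order autoregressive, scaled to unit marginal
variance so that the Matérn sigma remains the marginal standard deviation of
the separable space-time field built as a Kronecker product.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.linalg import cholesky, solve_triangular

from .mesh import Mesh

_MAX_KRON_DIM = 200_000  # guard against accidental huge products


def fem_matrices(mesh: Mesh):
    """Mass-lumped C (diagonal, as 1-D array) and stiffness G for linear basis."""
    tri = mesh.triangles
    p = mesh.nodes[tri]
    n = mesh.n_nodes
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    area = 0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
    # lumped mass: one third of the adjacent triangle areas per vertex
    c = np.zeros(n)
    np.add.at(c, tri.ravel(), np.repeat(area / 3.0, 3))
    # stiffness: G_ij = (e_i . e_j) / (4A), e_k the edge opposite vertex k
    e = np.stack([p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]],
                 axis=1)  # (ntri, 3, 2)
    rows, cols, vals = [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(tri[:, i])
            cols.append(tri[:, j])
            vals.append(np.einsum("nd,nd->n", e[:, i], e[:, j]) / (4.0 * area))
    G = sparse.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n)).tocsc()
    return c, G


def spde_precision(mesh: Mesh, range_m: float, sigma: float) -> sparse.csc_matrix:
    """Sparse precision of a Matérn (nu = 1) field on the mesh nodes."""
    if range_m <= 0 or sigma <= 0:
        raise ValueError("range_m and sigma must be positive")
    c, G = fem_matrices(mesh)
    kappa = np.sqrt(8.0) / range_m          # nu = 1 in 2D
    tau2 = 1.0 / (4.0 * np.pi * kappa ** 2 * sigma ** 2)
    Cinv = sparse.diags(1.0 / c)
    C = sparse.diags(c)
    Q = tau2 * (kappa ** 4 * C + 2.0 * kappa ** 2 * G + G @ Cinv @ G)
    Q = (Q + Q.T) * 0.5  # exact symmetry
    return Q.tocsc()


def ar1_precision(n_times: int, rho: float) -> sparse.csc_matrix:
    """Tridiagonal AR(1) precision scaled to unit marginal variance."""
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if n_times < 1:
        raise ValueError("n_times must be >= 1")
    if n_times == 1:
        return sparse.csc_matrix(np.array([[1.0]]))
    main = np.full(n_times, 1.0 + rho ** 2)
    main[0] = main[-1] = 1.0
    off = np.full(n_times - 1, -rho)
    Q = sparse.diags([off, main, off], offsets=[-1, 0, 1]) / (1.0 - rho ** 2)
    return Q.tocsc()


def kronecker_st_precision(Q_space: sparse.spmatrix,
                           Q_time: sparse.spmatrix) -> sparse.csc_matrix:
    """Separable space-time precision kron(Q_time, Q_space).

    Ordering is time-major: entry ``t * n_space + s`` is node ``s`` in year
    ``t``, matching the layout of the latent state vector.
    """
    dim = Q_space.shape[0] * Q_time.shape[0]
    if dim > _MAX_KRON_DIM:
        raise ValueError(f"space-time dimension {dim} exceeds the desk-scale "
                         f"guard ({_MAX_KRON_DIM})")
    Q = sparse.kron(Q_time, Q_space, format="csc")
    return ((Q + Q.T) * 0.5).tocsc()


def sample_gmrf(Q: sparse.spmatrix, n_samples: int, rng: np.random.Generator,
                mean: np.ndarray | None = None) -> np.ndarray:
    """Draw samples from N(mean, Q^{-1}) via a dense Cholesky of Q.

    Intended for desk-scale precisions (a few thousand dimensions); raises
    for singular Q.
    """
    Qd = Q.toarray() if sparse.issparse(Q) else np.asarray(Q)
    try:
        U = cholesky(Qd, lower=False)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix is singular or not positive "
                         "definite") from exc
    z = rng.standard_normal((Qd.shape[0], n_samples))
    x = solve_triangular(U, z, lower=False)
    if mean is not None:
        x = x + np.asarray(mean)[:, None]
    return x.T
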