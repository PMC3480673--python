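"""Trilinear (8-node isoparametric) hexahedral element machinery.

Shared by the excitation solver (scalar diffusion operator), the contraction
solver (vector elasticity operator) and the strain post-processing.  The
reference element is the bi-unit cube with local coordinates
``(xi, eta, zeta) in [-1, 1]^3`` and the VTK corner-node ordering
(bottom face counter-clockwise, then top face).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

# Corner signs of the 8 nodes in VTK ordering.
_SIGNS = np.array(
    [
        [-1, -1, -1],
        [+1, -1, -1],
        [+1, +1, -1],
        [-1, +1, -1],
        [-1, -1, +1],
        [+1, -1, +1],
        [+1, +1, +1],
        [-1, +1, +1],
    ],
    dtype=float,
)


def shape_functions(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear shape functions and their reference-coordinate gradients.

    Parameters
    ----------
    points : (..., 3) array of local coordinates.

    Returns
    -------
    N : (..., 8) values, dN : (..., 8, 3) gradients w.r.t. (xi, eta, zeta).
    """
    p = np.asarray(points, dtype=float)
    one = 1.0 + p[..., None, :] * _SIGNS  # (..., 8, 3)
    N = 0.125 * one[..., 0] * one[..., 1] * one[..., 2]
    dN = np.empty(one.shape)
    dN[..., 0] = 0.125 * _SIGNS[:, 0] * one[..., 1] * one[..., 2]
    dN[..., 1] = 0.125 * _SIGNS[:, 1] * one[..., 0] * one[..., 2]
    dN[..., 2] = 0.125 * _SIGNS[:, 2] * one[..., 0] * one[..., 1]
    return N, dN


@dataclass(frozen=True)
class ElementQuadrature:
    """Gauss–Legendre quadrature on the reference cube.

    ``weights`` sum to 8, the volume of the bi-unit cube.
    """

    points: np.ndarray  # (q, 3)
    weights: np.ndarray  # (q,)

    @classmethod
    def gauss(cls, n: int = 2) -> "ElementQuadrature":
        x, w = np.polynomial.legendre.leggauss(n)
        P = np.array([(a, b, c) for a in x for b in x for c in x])
        W = np.array([wa * wb * wc for wa in w for wb in w for wc in w])
        return cls(points=P, weights=W)


DEFAULT_QUADRATURE = ElementQuadrature.gauss(2)


def jacobians(coords: np.ndarray, quad: ElementQuadrature = DEFAULT_QUADRATURE):
    """Jacobian data at quadrature points for a batch of elements.

    Parameters
    ----------
    coords : (E, 8, 3) element corner coordinates.

    Returns
    -------
    detJ : (E, q), dN_dx : (E, q, 8, 3) physical shape-function gradients.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    _, dN = shape_functions(quad.points)  # (q, 8, 3)
    # J_ij = d x_i / d xi_j = sum_a coords[a, i] dN[a, j]
    J = np.einsum("eai,qaj->eqij", coords, dN)
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    dN_dx = np.einsum("qaj,eqji->eqai", dN, Jinv)
    return detJ, dN_dx


def element_volumes(coords: np.ndarray, quad: ElementQuadrature = DEFAULT_QUADRATURE) -> np.ndarray:
    detJ, _ = jacobians(coords, quad)
    return detJ @ quad.weights


def min_jacobian(coords: np.ndarray, quad: ElementQuadrature = DEFAULT_QUADRATURE) -> np.ndarray:
    """Minimum Jacobian determinant over quadrature points, per element."""
    detJ, _ = jacobians(coords, quad)
    return detJ.min(axis=1)


def map_local_to_global(coords: np.ndarray, xi: np.ndarray) -> np.ndarray:
    """Evaluate the trilinear map at local coordinates ``xi``."""
    N, _ = shape_functions(xi)
    return N @ coords


def invert_trilinear(coords: np.ndarray, x: np.ndarray, tol: float = 1e-12,
                     maxit: int = 30) -> tuple[np.ndarray, bool]:
    """Newton inversion of the trilinear map: find ``xi`` with ``x(xi) = x``.

    Returns the local coordinates and a convergence flag.  The result may lie
    outside the reference cube; callers decide containment with a tolerance.
    """
    xi = np.zeros(3)
    for _ in range(maxit):
        N, dN = shape_functions(xi)
        r = N @ coords - x
        if np.dot(r, r) < tol * tol:
            return xi, True
        J = np.einsum("ai,aj->ij", coords, dN)
        try:
            xi = xi - np.linalg.solve(J, r)
        except np.linalg.LinAlgError:
            return xi, False
    return xi, np.dot(r, r) < 1e-16


# ---------------------------------------------------------------------------
# Operator assembly
# ---------------------------------------------------------------------------

def assemble_scalar_stiffness(
    nodes: np.ndarray,
    elements: np.ndarray,
    tensors: np.ndarray,
    quad: ElementQuadrature = DEFAULT_QUADRATURE,
) -> sparse.csr_matrix:
    """FE stiffness of ``-div(D grad u)`` with a per-element 3x3 tensor ``D``.

    Natural (zero-flux) boundary conditions are implicit in the weak form.
    """
    coords = nodes[elements]  # (E, 8, 3)
    detJ, dN_dx = jacobians(coords, quad)
    w = detJ * quad.weights  # (E, q)
    Ke = np.einsum("eqai,eij,eqbj,eq->eab", dN_dx, tensors, dN_dx, w)
    E, n = elements.shape
    rows = np.repeat(elements, n, axis=1).ravel()
    cols = np.tile(elements, (1, n)).ravel()
    A = sparse.coo_matrix((Ke.ravel(), (rows, cols)), shape=(len(nodes), len(nodes)))
    return A.tocsr()


def lumped_mass(
    nodes: np.ndarray,
    elements: np.ndarray,
    quad: ElementQuadrature = DEFAULT_QUADRATURE,
) -> np.ndarray:
    """Row-sum (lumped) mass vector: ``m_a = integral N_a dV``."""
    coords = nodes[elements]
    detJ, _ = jacobians(coords, quad)
    N, _ = shape_functions(quad.points)  # (q, 8)
    me = np.einsum("qa,eq,q->ea", N, detJ, quad.weights)
    m = np.zeros(len(nodes))
    np.add.at(m, elements.ravel(), me.ravel())
    return m


def strain_displacement_matrices(dN_dx: np.ndarray) -> np.ndarray:
    """Small-strain B matrices (Voigt order xx, yy, zz, yz, xz, xy).

    Parameters
    ----------
    dN_dx : (..., 8, 3) physical shape-function gradients.

    Returns
    -------
    B : (..., 6, 24) with engineering shear rows.
    """
    shp = dN_dx.shape[:-2]
    B = np.zeros(shp + (6, 24))
    dx, dy, dz = dN_dx[..., 0], dN_dx[..., 1], dN_dx[..., 2]
    ax = np.arange(8)
    B[..., 0, 3 * ax + 0] = dx
    B[..., 1, 3 * ax + 1] = dy
    B[..., 2, 3 * ax + 2] = dz
    B[..., 3, 3 * ax + 1] = dz
    B[..., 3, 3 * ax + 2] = dy
    B[..., 4, 3 * ax + 0] = dz
    B[..., 4, 3 * ax + 2] = dx
    B[..., 5, 3 * ax + 0] = dy
    B[..., 5, 3 * ax + 1] = dx
    return B
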