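"""Hexahedral element stiffness kernel and isotropic elasticity matrix.

The 24x24 unit-modulus kernel K of a cubic 8-node brick element with
tri-linear shape functions satisfies ``F = E_elem * K @ u`` for the 24
vertex displacements/forces.  It is identical for all elements up to the
modulus scale factor, so it is computed once per (Poisson ratio, edge
length) and cached.

Voigt order is (xx, yy, zz, yz, xz, xy) with engineering shear strains
(gamma = 2 eps).  Local dof order is vertex-major with direction innermost;
vertex n sits at offset ``model._VERTEX_OFFSETS[n]`` (x varying fastest).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .model import _VERTEX_OFFSETS

__all__ = [
    "isotropic_elasticity",
    "unit_kernel",
    "element_forces",
    "element_strain_energy",
]


def isotropic_elasticity(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic Hooke matrix (MPa) in Voigt order.

    Diagonal normal terms ``E(1-nu)/((1+nu)(1-2nu))``, off-diagonal normal
    terms ``E nu/((1+nu)(1-2nu))``, shear diagonal ``E/(2(1+nu))``.
    """
    if E < 0:
        raise ValueError("Young's modulus must be nonnegative")
    if not (0.0 <= nu < 0.5):
        raise ValueError("Poisson ratio must be in [0, 0.5) (incompressible limit excluded)")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] = lam + 2.0 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def _shape_gradients(xi: float, eta: float, zeta: float, edge: float) -> np.ndarray:
    """Gradients dN_n/dx_d of the 8 tri-linear shape functions, shape (8, 3).

    Natural coordinates run over [0, 1]^3; physical = natural * edge.
    """
    g = np.empty((8, 3))
    for n, (a, b, c) in enumerate(_VERTEX_OFFSETS):
        fx = xi if a else 1.0 - xi
        fy = eta if b else 1.0 - eta
        fz = zeta if c else 1.0 - zeta
        dfx = 1.0 if a else -1.0
        dfy = 1.0 if b else -1.0
        dfz = 1.0 if c else -1.0
        g[n] = (dfx * fy * fz, fx * dfy * fz, fx * fy * dfz)
    return g / edge


def _b_matrix(grad: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6, 24) for given shape gradients."""
    B = np.zeros((6, 24))
    for n in range(8):
        gx, gy, gz = grad[n]
        c = 3 * n
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c + 1] = gz  # gamma_yz = du_y/dz + du_z/dy
        B[3, c + 2] = gy
        B[4, c] = gz  # gamma_xz
        B[4, c + 2] = gx
        B[5, c] = gy  # gamma_xy
        B[5, c + 1] = gx
    return B


@lru_cache(maxsize=32)
def unit_kernel(nu: float, edge: float = 1.0) -> np.ndarray:
    """24x24 stiffness kernel of a unit-modulus cube element.

    ``K = integral of B^T C B`` over the cube, by 2x2x2 Gauss quadrature
    (exact for this polynomial integrand).  Symmetric positive
    semi-definite with a 6-dimensional rigid-body null space; scales
    linearly with edge length.  The returned array is cached and marked
    read-only.
    """
    if not edge > 0:
        raise ValueError("edge length must be positive")
    C = isotropic_elasticity(1.0, nu)
    gp = 0.5 + np.array([-1.0, 1.0]) / (2.0 * np.sqrt(3.0))  # on [0, 1]
    K = np.zeros((24, 24))
    w = (edge**3) / 8.0  # weight * |J| per Gauss point
    for xi in gp:
        for eta in gp:
            for zeta in gp:
                B = _b_matrix(_shape_gradients(xi, eta, zeta, edge))
                K += w * (B.T @ C @ B)
    K = 0.5 * (K + K.T)
    K.setflags(write=False)
    return K


def element_forces(kernel: np.ndarray, modulus: float, u_elem: np.ndarray) -> np.ndarray:
    """Vertex forces (N, for mm/MPa inputs) induced by element displacements."""
    return modulus * (kernel @ u_elem)


def element_strain_energy(kernel: np.ndarray, modulus: float, u_elem: np.ndarray) -> float:
    """Strain energy 0.5 E u^T K u (N.mm); nonnegative by PSD of K."""
    return 0.5 * modulus * float(u_elem @ kernel @ u_elem)
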