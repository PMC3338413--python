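"""Matrix-free element-by-element macroscopic stiffness operator.

The equilibrium system ``A U = B`` on the free variables is never
assembled: applying A loops (vectorized) over elements, gathering the 24
local displacements, multiplying by the shared modulus-scaled kernel and
scatter-adding back.  Prescribed dofs contribute zero inside ``apply`` and
generate the right-hand side ``B`` instead.  An explicit scipy.sparse
assembly is provided for small-instance verification only; the solver
never touches it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .kernel import unit_kernel
from .model import _VERTEX_OFFSETS, BoundarySpec, DofMap, MaterialLaw, VoxelModel

__all__ = ["EBEOperator", "PreconditionerDiag"]


@dataclass(frozen=True)
class PreconditionerDiag:
    """Inverse diagonal of A (the Jacobi preconditioner vector)."""

    inv_diag: np.ndarray

    def apply(self, r: np.ndarray) -> np.ndarray:
        return self.inv_diag * r


class EBEOperator:
    """Element-by-element application of the macroscopic stiffness matrix.

    Symmetric, and positive definite on the free variables of an anchored
    structure (positive semi-definite when rigid in-plane modes are left
    unconstrained by frictionless end conditions; the compression
    right-hand side is orthogonal to those modes).
    """

    def __init__(self, model: VoxelModel, law: MaterialLaw, dofmap: DofMap):
        self.model = model
        self.law = law
        self.dofmap = dofmap
        self.kernel = unit_kernel(law.poisson_ratio, model.voxel_size)

        elems = dofmap.elements  # (M, 3), raster order (fixed scatter order)
        self.moduli = law.modulus_map(model)[elems[:, 0], elems[:, 1], elems[:, 2]]
        if np.any(self.moduli <= 0):
            raise ValueError("inactive element in dof map")

        # (M, 8, 3) vertex indices, then (M, 24) global dof gather tables
        verts = elems[:, None, :] + _VERTEX_OFFSETS[None, :, :]
        vi, vj, vk = verts[..., 0], verts[..., 1], verts[..., 2]
        vid = dofmap.var_id[vi, vj, vk, :].reshape(-1, 24)  # -1 where constrained
        self.n_free = dofmap.n_free
        # constrained dofs map to a padding slot that reads/accumulates zero
        self._gather = np.where(vid >= 0, vid, self.n_free)
        self._pres = dofmap.prescribed[vi, vj, vk, :].reshape(-1, 24)
        # linear indices into the full (Vx, Vy, Vz, 3) vertex field
        vx, vy, vz = dofmap.var_id.shape[:3]
        lin = ((vi * vy + vj) * vz + vk) * 3
        self._full_idx = (lin[..., None] + np.arange(3)).reshape(-1, 24)
        self._n_full = vx * vy * vz * 3

    # -- core products ---------------------------------------------------

    def _gather_free(self, u: np.ndarray) -> np.ndarray:
        u_pad = np.append(u, 0.0)
        return u_pad[self._gather]

    def _scatter_free(self, fe: np.ndarray, gather: np.ndarray | None = None) -> np.ndarray:
        g = self._gather if gather is None else gather
        out = np.bincount(g.ravel(), weights=fe.ravel(), minlength=self.n_free + 1)
        return out[: self.n_free]

    def apply(self, u: np.ndarray) -> np.ndarray:
        """A @ u on the free variables (prescribed dofs contribute zero)."""
        if u.shape != (self.n_free,):
            raise ValueError("vector length does not match number of free variables")
        ue = self._gather_free(u)
        fe = (ue @ self.kernel) * self.moduli[:, None]
        return self._scatter_free(fe)

    def rhs_from_bcs(self, bcs: BoundarySpec | None = None) -> np.ndarray:
        """Right-hand side B induced by the prescribed displacements.

        B is minus the free-dof forces generated when prescribed dofs take
        their boundary values and free dofs are zero, so that the solution
        of ``A U = B`` is the equilibrium displacement field.  The boundary
        values are the ones recorded in the dof map; ``bcs`` is accepted
        for interface clarity and consistency-checked.
        """
        if bcs is not None:
            vals = self.dofmap.prescribed[
                bcs.vertices[:, 0], bcs.vertices[:, 1], bcs.vertices[:, 2], bcs.directions
            ]
            if not np.allclose(vals, bcs.values):
                raise ValueError("boundary spec inconsistent with dof map")
        fe = (self._pres @ self.kernel) * self.moduli[:, None]
        return -self._scatter_free(fe)

    def jacobi_diagonal(self) -> PreconditionerDiag:
        """Inverse of the assembled diagonal of A.

        A zero or negative diagonal entry indicates a floating dof that
        pruning should have removed, and raises.
        """
        dk = np.diag(self.kernel)
        contrib = self.moduli[:, None] * dk[None, :]
        diag = self._scatter_free(contrib)
        if np.any(diag <= 0):
            raise ValueError("non-positive stiffness diagonal: structure not pruned/anchored")
        return PreconditionerDiag(inv_diag=1.0 / diag)

    def total_vertex_forces(self, full_u: np.ndarray) -> np.ndarray:
        """Element-induced force sums at every vertex, shape (Vx, Vy, Vz, 3).

        At equilibrium these vanish at free dofs and equal the reaction
        forces at constrained dofs.
        """
        if full_u.shape != self.dofmap.var_id.shape:
            raise ValueError("full displacement field has wrong shape")
        ue = full_u.ravel()[self._full_idx]
        fe = (ue @ self.kernel) * self.moduli[:, None]
        out = np.bincount(self._full_idx.ravel(), weights=fe.ravel(), minlength=self._n_full)
        return out.reshape(full_u.shape)

    def strain_energies(self, full_u: np.ndarray) -> np.ndarray:
        """Per-active-element strain energies 0.5 E u^T K u, shape (N_e,)."""
        ue = full_u.ravel()[self._full_idx]
        return 0.5 * self.moduli * np.einsum("mi,ij,mj->m", ue, self.kernel, ue)

    # -- verification-only explicit form ---------------------------------

    def assemble(self) -> sp.csr_matrix:
        """Explicit sparse A on the free variables (small-instance oracle).

        This is the full-matrix storage scheme the element-by-element
        formulation avoids; it exists solely to cross-check ``apply`` and
        the preconditioner on tiny models and is never used by the solver.
        """
        g = self._gather
        rows = np.repeat(g, 24, axis=1).ravel()
        cols = np.tile(g, (1, 24)).ravel()
        vals = (self.moduli[:, None, None] * self.kernel[None, :, :]).ravel()
        keep = (rows < self.n_free) & (cols < self.n_free)
        A = sp.coo_matrix(
            (vals[keep], (rows[keep], cols[keep])), shape=(self.n_free, self.n_free)
        )
        return A.tocsr()
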