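"""Voxel structural model, material law, boundary conditions and dof numbering.

The structural model is the one-voxel-one-element convention of image-based
micro-FE: a 3D grid of bone-volume fraction (BVF) values in [0, 1], each
positive voxel becoming a single hexahedral element whose Young's modulus is
scaled by BVF (grayscale mode) or thresholded (binary mode).

Vertex (i, j, k) is the lower corner of voxel (i, j, k); the physical
coordinate of a vertex is ``index * voxel_size``.  Free displacement
variables are numbered densely in raster order over vertices (z slowest,
then y, then x) with the displacement direction as the innermost index, so
the 24 variable indices of an element can be recovered from 4 base indices
by offsetting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelModel",
    "MaterialLaw",
    "BoundarySpec",
    "DofMap",
    "element_modulus",
    "active_mask",
    "active_elements",
    "prune_unanchored",
    "build_dof_map",
]

logger = logging.getLogger(__name__)

#: Local vertex offsets of a hexahedral element, x fastest.  Local dof
#: ``3 * n + d`` is direction ``d`` at vertex ``_VERTEX_OFFSETS[n]``; the
#: element kernel uses the same ordering.
_VERTEX_OFFSETS = np.array(
    [
        (0, 0, 0),
        (1, 0, 0),
        (0, 1, 0),
        (1, 1, 0),
        (0, 0, 1),
        (1, 0, 1),
        (0, 1, 1),
        (1, 1, 1),
    ],
    dtype=np.int64,
)

# 26-connectivity: elements sharing any vertex are coupled in the stiffness
# graph, so pruning must treat them as connected.
_VERTEX_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VoxelModel:
    """A 3D bone-volume-fraction grid with isotropic voxel size.

    Parameters
    ----------
    bvf:
        Array of shape ``(Nx, Ny, Nz)`` with values in [0, 1]
        (dimensionless volume fraction).
    voxel_size:
        Physical edge length of a voxel in mm (isotropic; the element
        kernel derivation assumes a cube).
    """

    bvf: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        bvf = np.asarray(self.bvf, dtype=np.float64)
        if bvf.ndim != 3 or min(bvf.shape) < 1:
            raise ValueError("bvf must be a 3D array with all dims >= 1")
        if not np.all(np.isfinite(bvf)):
            raise ValueError("bvf contains non-finite values")
        if bvf.min() < 0.0 or bvf.max() > 1.0:
            raise ValueError("bvf values must lie in [0, 1]")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        object.__setattr__(self, "bvf", bvf)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.bvf.shape  # type: ignore[return-value]

    @property
    def vertex_dims(self) -> tuple[int, int, int]:
        nx, ny, nz = self.dims
        return (nx + 1, ny + 1, nz + 1)

    def physical_length(self, axis: int) -> float:
        """Edge length of the image volume along ``axis`` in mm."""
        return self.dims[axis] * self.voxel_size


@dataclass(frozen=True)
class MaterialLaw:
    """Voxel-wise isotropic material law.

    In grayscale mode the element modulus is ``tissue_modulus * BVF``; in
    binary mode it is ``tissue_modulus`` for ``BVF >= binary_threshold``
    and zero otherwise.  Tissue-level anisotropy is deliberately not
    modeled: each voxel is an isotropic continuum.
    """

    tissue_modulus: float = 15000.0  # MPa at BVF = 1
    poisson_ratio: float = 0.3
    mode: str = "grayscale"
    binary_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.tissue_modulus > 0:
            raise ValueError("tissue_modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must be in [0, 0.5)")
        if self.mode not in ("grayscale", "binary"):
            raise ValueError(f"unknown material mode {self.mode!r}")
        if not (0.0 < self.binary_threshold <= 1.0):
            raise ValueError("binary_threshold must be in (0, 1]")

    def modulus_map(self, model: VoxelModel) -> np.ndarray:
        """Per-voxel Young's modulus (MPa), zero for inactive voxels."""
        if self.mode == "grayscale":
            return self.tissue_modulus * model.bvf
        return np.where(model.bvf >= self.binary_threshold, self.tissue_modulus, 0.0)


def element_modulus(model: VoxelModel, law: MaterialLaw, element: tuple[int, int, int]) -> float:
    """Young's modulus of a single element (MPa)."""
    return float(law.modulus_map(model)[tuple(element)])


def active_mask(model: VoxelModel, law: MaterialLaw) -> np.ndarray:
    """Boolean mask of voxels that carry an element (positive modulus)."""
    return law.modulus_map(model) > 0.0


def active_elements(model: VoxelModel, law: MaterialLaw) -> np.ndarray:
    """Indices of active elements as an ``(M, 3)`` int array (raster order).

    Raises ``ValueError`` if the model contains no material.
    """
    mask = active_mask(model, law)
    idx = np.argwhere(mask)
    if idx.shape[0] == 0:
        raise ValueError("no material: model has no active elements")
    return idx


@dataclass(frozen=True)
class BoundarySpec:
    """Prescribed vertex displacements defining the load case.

    ``vertices[m]`` is an ``(i, j, k)`` vertex index, ``directions[m]`` a
    direction in {0, 1, 2}, ``values[m]`` the prescribed displacement in mm.
    ``strain`` and ``axis`` record the macroscopic load the entries encode
    (used for stress normalization and per-level regeneration).
    """

    vertices: np.ndarray  # (M, 3) int
    directions: np.ndarray  # (M,) int
    values: np.ndarray  # (M,) float, mm
    strain: float = 0.0
    axis: int = 2

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vertices, dtype=np.int64))
        d = np.asarray(self.directions, dtype=np.int64).ravel()
        u = np.asarray(self.values, dtype=np.float64).ravel()
        if v.shape != (d.size, 3) or u.size != d.size:
            raise ValueError("inconsistent boundary entry arrays")
        if d.size == 0:
            raise ValueError("boundary specification is empty")
        keys = np.concatenate([v, d[:, None]], axis=1)
        if np.unique(keys, axis=0).shape[0] != keys.shape[0]:
            raise ValueError("duplicate (vertex, direction) boundary entries")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "values", u)

    def __len__(self) -> int:
        return int(self.directions.size)


def _vertex_active_mask(elem_mask: np.ndarray) -> np.ndarray:
    """Vertices belonging to at least one active element."""
    nx, ny, nz = elem_mask.shape
    vmask = np.zeros((nx + 1, ny + 1, nz + 1), dtype=bool)
    for di, dj, dk in _VERTEX_OFFSETS:
        vmask[di : nx + di, dj : ny + dj, dk : nz + dk] |= elem_mask
    return vmask


def prune_unanchored(
    model: VoxelModel, law: MaterialLaw, bcs: BoundarySpec
) -> VoxelModel:
    """Remove connected components of elements with no constrained vertex.

    Elements are connected when they share a vertex (26-connectivity), the
    weakest coupling present in the stiffness graph; any component not
    touching a constrained vertex would make the system singular.  Returns
    a model with the BVF of removed voxels set to zero; the number of
    removed components is logged.  Raises if nothing remains anchored.
    """
    mask = active_mask(model, law)
    labels, n_comp = ndimage.label(mask, structure=_VERTEX_CONNECTIVITY)
    if n_comp == 0:
        raise ValueError("no material: model has no active elements")

    nx, ny, nz = model.dims
    anchored: set[int] = set()
    for (i, j, k) in bcs.vertices:
        # the up-to-8 voxels sharing vertex (i, j, k)
        for di, dj, dk in _VERTEX_OFFSETS:
            vi, vj, vk = i - di, j - dj, k - dk
            if 0 <= vi < nx and 0 <= vj < ny and 0 <= vk < nz:
                lab = labels[vi, vj, vk]
                if lab:
                    anchored.add(int(lab))
    if not anchored:
        raise ValueError("structure not anchored: no component touches a constrained vertex")

    keep = np.isin(labels, sorted(anchored))
    removed = n_comp - len(anchored)
    if removed:
        logger.info("pruned %d unanchored component(s)", removed)
        bvf = np.where(keep, model.bvf, 0.0)
        return replace(model, bvf=bvf)
    return model


@dataclass
class DofMap:
    """Dense numbering of free (vertex, direction) variables.

    ``var_id[i, j, k, d]`` is the variable id (>= 0) of a free dof, -1 for
    constrained or inactive dofs.  ``prescribed`` holds boundary values at
    constrained dofs (0 elsewhere).  Ids follow raster order over vertices
    (z slowest, x fastest is reversed: z, then y, then x) with direction
    innermost, matching the base-index offsetting storage scheme.
    """

    var_id: np.ndarray  # (Vx, Vy, Vz, 3) int64
    prescribed: np.ndarray  # (Vx, Vy, Vz, 3) float64
    constrained: np.ndarray  # (Vx, Vy, Vz, 3) bool
    elements: np.ndarray  # (N_e, 3) int64, raster order
    n_free: int
    free_coords: np.ndarray = field(repr=False, default=None)  # (N_v, 4)

    @property
    def n_elements(self) -> int:
        return int(self.elements.shape[0])

    def variable_index(self, i: int, j: int, k: int, d: int) -> int | None:
        """Variable id of a dof, or ``None`` if constrained/inactive."""
        vid = int(self.var_id[i, j, k, d])
        return vid if vid >= 0 else None

    def lookup(self, vid: int) -> tuple[int, int, int, int]:
        """Reverse lookup: variable id -> (i, j, k, direction)."""
        return tuple(int(x) for x in self.free_coords[vid])  # type: ignore[return-value]

    def full_field(self, u: np.ndarray) -> np.ndarray:
        """Embed a free-variable vector into the full vertex field.

        Returns a ``(Vx, Vy, Vz, 3)`` array with prescribed values at
        constrained dofs, solver values at free dofs and 0 elsewhere.
        """
        if u.shape != (self.n_free,):
            raise ValueError("free-variable vector has wrong length")
        full = self.prescribed.copy()
        free = self.var_id >= 0
        full[free] = u[self.var_id[free]]
        return full

    def extract_free(self, full: np.ndarray) -> np.ndarray:
        """Gather the free dofs of a full vertex field into a vector."""
        free = self.var_id >= 0
        out = np.zeros(self.n_free)
        out[self.var_id[free]] = full[free]
        return out


def build_dof_map(model: VoxelModel, law: MaterialLaw, bcs: BoundarySpec) -> DofMap:
    """Number the free variables of an (already pruned) model.

    Every (vertex, direction) pair of an active-element vertex is either a
    free variable (dense id) or a constrained dof with its prescribed value
    recorded.  Boundary entries on inactive vertices are rejected.
    """
    mask = active_mask(model, law)
    elements = np.argwhere(mask)
    if elements.shape[0] == 0:
        raise ValueError("no material: model has no active elements")
    vmask = _vertex_active_mask(mask)

    vdims = model.vertex_dims
    constrained = np.zeros(vdims + (3,), dtype=bool)
    prescribed = np.zeros(vdims + (3,), dtype=np.float64)
    vi, vj, vk = bcs.vertices[:, 0], bcs.vertices[:, 1], bcs.vertices[:, 2]
    if not np.all(vmask[vi, vj, vk]):
        raise ValueError("boundary conditions reference inactive vertices")
    constrained[vi, vj, vk, bcs.directions] = True
    prescribed[vi, vj, vk, bcs.directions] = bcs.values

    free = vmask[..., None] & ~constrained
    # raster numbering: z slowest, then y, then x, direction innermost
    free_t = free.transpose(2, 1, 0, 3)
    flat = free_t.ravel()
    ids_flat = np.where(flat, np.cumsum(flat) - 1, -1)
    var_id = ids_flat.reshape(free_t.shape).transpose(2, 1, 0, 3).astype(np.int64)
    n_free = int(flat.sum())

    kji_d = np.argwhere(free_t)  # rows ordered by id
    free_coords = kji_d[:, [2, 1, 0, 3]].astype(np.int64)

    return DofMap(
        var_id=var_id,
        prescribed=prescribed,
        constrained=constrained,
        elements=elements.astype(np.int64),
        n_free=n_free,
        free_coords=free_coords,
    )
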