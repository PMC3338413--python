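"""Simulated uniaxial compression testing and post-processing.

Pipeline: generate boundary conditions encoding a macroscopic compressive
strain along one image axis, solve for equilibrium displacements, then
report the apparent axial stiffness (total stress / applied strain, MPa)
and optionally a per-element strain-energy map.

Total stress is the sum of axial reaction forces over the displaced face
divided by the full image cross-sectional area (apparent stress); the sign
convention is compression positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    BoundarySpec,
    DofMap,
    MaterialLaw,
    VoxelModel,
    _vertex_active_mask,
    active_mask,
    build_dof_map,
    prune_unanchored,
)
from .operator import EBEOperator
from .solver import ConvergenceTrace

__all__ = [
    "UniaxialCompression",
    "SolveResult",
    "uniaxial_compression_bcs",
    "total_stress",
    "apparent_stiffness",
    "strain_energy_map",
    "stress_functional",
    "cross_section_area",
]


@dataclass(frozen=True)
class UniaxialCompression:
    """Macroscopic uniaxial compression load descriptor.

    ``strain`` is the applied compressive strain (dimensionless, e.g. 0.01
    for 1%), ``axis`` the image axis of loading, and ``end_condition``
    either ``"axial-only"`` (frictionless platens: only the axial
    direction is prescribed on the end faces) or ``"clamped"`` (all three
    directions fixed on both faces).
    """

    strain: float = 0.01
    axis: int = 2
    end_condition: str = "axial-only"

    def __post_init__(self) -> None:
        if not (0.0 <= self.strain < 0.1):
            raise ValueError("strain must be in [0, 0.1)")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        if self.end_condition not in ("axial-only", "clamped"):
            raise ValueError("end_condition must be 'axial-only' or 'clamped'")

    def bcs(self, model: VoxelModel, law: MaterialLaw) -> BoundarySpec:
        return uniaxial_compression_bcs(
            model, law, self.strain, self.axis, self.end_condition
        )


def uniaxial_compression_bcs(
    model: VoxelModel,
    law: MaterialLaw,
    strain: float,
    axis: int = 2,
    end_condition: str = "axial-only",
) -> BoundarySpec:
    """Boundary conditions for axial compression between two platens.

    Active vertices on the minimal face get axial displacement 0; active
    vertices on the maximal face get ``-strain * L`` where L is the
    physical length of the volume along the load axis.  In clamped mode
    the transverse directions are additionally fixed to zero on both
    faces.
    """
    load = UniaxialCompression(strain=strain, axis=axis, end_condition=end_condition)
    vmask = _vertex_active_mask(active_mask(model, law))
    n_axis = model.dims[axis]

    faces = []
    for face_idx, disp in ((0, 0.0), (n_axis, -strain * model.physical_length(axis))):
        sel = [slice(None)] * 3
        sel[axis] = face_idx
        face_verts = np.argwhere(vmask[tuple(sel)])
        if face_verts.shape[0] == 0:
            raise ValueError("structure does not span load axis: empty loaded face")
        verts = np.insert(face_verts, axis, face_idx, axis=1)
        faces.append((verts, disp))

    dirs_per_vertex = (axis,) if load.end_condition == "axial-only" else (0, 1, 2)
    vertices, directions, values = [], [], []
    for verts, disp in faces:
        for d in dirs_per_vertex:
            vertices.append(verts)
            directions.append(np.full(verts.shape[0], d))
            values.append(np.full(verts.shape[0], disp if d == axis else 0.0))
    return BoundarySpec(
        vertices=np.concatenate(vertices),
        directions=np.concatenate(directions),
        values=np.concatenate(values),
        strain=strain,
        axis=axis,
    )


def cross_section_area(model: VoxelModel, axis: int) -> float:
    """Full image cross-section perpendicular to the load axis (mm^2)."""
    dims = list(model.dims)
    dims.pop(axis)
    return dims[0] * dims[1] * model.voxel_size**2


def total_stress(
    op: EBEOperator, full_u: np.ndarray, bcs: BoundarySpec, model: VoxelModel
) -> float:
    """Apparent total stress (MPa), compression positive.

    Sum of axial reaction forces over the displaced (maximal) face
    constrained vertices, normalized by the full cross-sectional area.
    """
    forces = op.total_vertex_forces(full_u)
    axis = bcs.axis
    top = model.dims[axis]
    sel = [slice(None)] * 4
    sel[axis] = top
    sel[3] = axis
    face_forces = forces[tuple(sel)]
    return -float(face_forces.sum()) / cross_section_area(model, axis)


def apparent_stiffness(stress: float, strain: float) -> float:
    """Macroscopic stress/strain ratio (MPa)."""
    if strain == 0:
        raise ValueError("apparent stiffness undefined at zero strain")
    return stress / strain


def strain_energy_map(op: EBEOperator, full_u: np.ndarray, model: VoxelModel) -> np.ndarray:
    """Per-voxel element strain energy (N.mm); inactive voxels are zero."""
    energies = op.strain_energies(full_u)
    emap = np.zeros(model.dims)
    e = op.dofmap.elements
    emap[e[:, 0], e[:, 1], e[:, 2]] = energies
    return emap


def stress_functional(op: EBEOperator, bcs: BoundarySpec, model: VoxelModel):
    """Total stress as an affine functional of the free variables.

    Because reaction forces are linear in the displacements, the stress at
    iterate u is ``g . u + s0``.  Precomputing (g, s0) makes per-iteration
    stress monitoring a single dot product instead of a full element pass.
    Returns ``monitor(iteration, u) -> stress``.
    """
    axis = bcs.axis
    top = model.dims[axis]
    dofmap = op.dofmap
    # indicator of the top-face constrained axial dofs in the full field
    sel_full = np.zeros(dofmap.var_id.shape)
    sel = [slice(None)] * 4
    sel[axis] = top
    sel[3] = axis
    sel_full[tuple(sel)] = 1.0
    # per-element contraction against the indicator rows of the kernel
    se = sel_full.ravel()[op._full_idx]  # (M, 24)
    w = (se @ op.kernel) * op.moduli[:, None]  # rows of A hit by the selector
    g_full = np.bincount(
        op._full_idx.ravel(), weights=w.ravel(), minlength=op._n_full
    ).reshape(dofmap.var_id.shape)
    area = cross_section_area(model, axis)
    g = -dofmap.extract_free(g_full) / area
    s0 = -float((g_full * dofmap.prescribed).sum()) / area

    def monitor(_it: int, u: np.ndarray) -> float:
        return float(g @ u) + s0

    return monitor


@dataclass
class SolveResult:
    """Outcome of a simulated compression test."""

    displacements: np.ndarray  # full (Vx, Vy, Vz, 3) field, mm
    stiffness: float  # apparent axial stiffness, MPa
    stress: float  # total stress, MPa (compression positive)
    strain: float
    iterations_per_level: list[int] = field(default_factory=list)
    converged: bool = False
    trace: ConvergenceTrace | None = None
    energy_map: np.ndarray | None = None
    model: VoxelModel | None = None

    @property
    def total_iterations(self) -> int:
        return sum(self.iterations_per_level)
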