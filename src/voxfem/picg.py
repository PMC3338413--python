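"""Pre-iteration on coarser grids (PICG).

Instead of iterating directly on the full-resolution model, the model is
downsampled by a schedule of factors (default ``[4, 2, 1]``), a fixed
number of CG iterations (default 200) is run on each coarse level, and the
resulting displacement field is tri-linearly interpolated onto the next
finer grid as a warm start.  The finest level runs under the ordinary
stopping policy.  This is a warm-start scheme, not a multigrid cycle: no
residual restriction takes place.

Coarse BVF is the block mean (the volume-fraction-preserving choice);
grids are zero-padded to a multiple of the factor, which only adds
inactive material.  Boundary conditions are regenerated per level for the
same macroscopic strain, and coarse levels always use grayscale material
scaling since block averaging produces fractional BVF.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .mechanics import (
    SolveResult,
    UniaxialCompression,
    apparent_stiffness,
    strain_energy_map,
    stress_functional,
    total_stress,
    uniaxial_compression_bcs,
)
from .model import BoundarySpec, MaterialLaw, VoxelModel, build_dof_map, prune_unanchored
from .operator import EBEOperator
from .solver import Partition, StoppingPolicy, partition_z, partitioned_pcg, pcg_solve

__all__ = [
    "GridSchedule",
    "downsample_model",
    "coarse_bcs",
    "prolong",
    "picg_solve",
]


@dataclass(frozen=True)
class GridSchedule:
    """Ordered downsampling factors ending in 1, e.g. ``(4, 2, 1)``.

    ``coarse_iterations`` is the fixed CG budget on every level except the
    finest, which runs under the caller's stopping policy.
    """

    factors: tuple[int, ...] = (4, 2, 1)
    coarse_iterations: int = 200

    def __post_init__(self) -> None:
        f = tuple(int(x) for x in self.factors)
        if len(f) == 0 or f[-1] != 1:
            raise ValueError("schedule must end with factor 1")
        if any(x <= 0 for x in f):
            raise ValueError("factors must be positive integers")
        if any(a <= b for a, b in zip(f, f[1:])):
            raise ValueError("factors must be strictly decreasing")
        if self.coarse_iterations < 1:
            raise ValueError("coarse_iterations must be >= 1")
        object.__setattr__(self, "factors", f)


def downsample_model(model: VoxelModel, f: int) -> VoxelModel:
    """Block-mean downsampling by an integer factor.

    The grid is zero-padded to a multiple of f (adding only empty voxels);
    coarse BVF is the mean over each f^3 block and the coarse voxel size
    is ``f * voxel_size``, so physical extent is preserved up to padding.
    """
    if f < 1:
        raise ValueError("downsampling factor must be >= 1")
    if f == 1:
        return model
    nx, ny, nz = model.dims
    pad = [(0, (-d) % f) for d in model.dims]
    bvf = np.pad(model.bvf, pad)
    cx, cy, cz = (s // f for s in bvf.shape)
    coarse = bvf.reshape(cx, f, cy, f, cz, f).mean(axis=(1, 3, 5))
    return VoxelModel(bvf=coarse, voxel_size=model.voxel_size * f)


def coarse_bcs(
    load: UniaxialCompression, coarse_model: VoxelModel, law: MaterialLaw
) -> BoundarySpec:
    """Regenerate the compression boundary conditions at a coarse level.

    The same macroscopic strain is applied; since the coarse grid spans
    the same physical length (up to inactive padding), the prescribed face
    displacement matches the fine level's physical value.
    """
    return load.bcs(coarse_model, law)


def prolong(
    u_coarse: np.ndarray, coarse_model: VoxelModel, fine_model: VoxelModel, f: int
) -> np.ndarray:
    """Tri-linear interpolation of a coarse vertex field onto fine vertices.

    ``u_coarse`` is a full ``(Vcx, Vcy, Vcz, 3)`` displacement field (mm;
    zeros at inactive coarse vertices).  Fine vertex (i, j, k) sits at
    coarse fractional index ``(i/f, j/f, k/f)``; displacements are
    physical, so no rescaling is applied.  Fine vertices coincident with
    coarse vertices receive exactly the coarse values; vertices outside
    the coarse active support get (near-)zero from the zero-filled field.
    """
    vcd = tuple(d + 1 for d in coarse_model.dims)
    if u_coarse.shape != vcd + (3,):
        raise ValueError("coarse displacement field has wrong shape")
    fine_vdims = fine_model.vertex_dims
    coords = np.meshgrid(
        *(np.arange(n) / f for n in fine_vdims), indexing="ij"
    )
    coords = np.stack([c.ravel() for c in coords])
    out = np.empty(fine_vdims + (3,))
    for d in range(3):
        out[..., d] = ndimage.map_coordinates(
            u_coarse[..., d], coords, order=1, mode="nearest"
        ).reshape(fine_vdims)
    return out


def picg_solve(
    model: VoxelModel,
    law: MaterialLaw,
    load: UniaxialCompression,
    schedule: GridSchedule | None = None,
    policy: StoppingPolicy | None = None,
    workers: int = 1,
    compute_energy_map: bool = False,
) -> SolveResult:
    """Full compression pipeline with coarse-to-fine warm starts.

    With ``schedule == GridSchedule((1,))`` this is a plain single-grid
    solve.  ``workers`` > 1 runs the finest level under the partitioned
    execution contract (deterministic, K Z-slab sub-regions).
    """
    schedule = schedule or GridSchedule()
    policy = policy or StoppingPolicy()

    u_prev_full: np.ndarray | None = None
    prev_model: VoxelModel | None = None
    prev_factor = 1
    iterations_per_level: list[int] = []
    last: dict = {}

    for level, f in enumerate(schedule.factors):
        finest = f == 1
        m = downsample_model(model, f)
        law_level = law if finest else replace(law, mode="grayscale")
        bcs = load.bcs(m, law_level)
        m = prune_unanchored(m, law_level, bcs)
        dofmap = build_dof_map(m, law_level, bcs)
        op = EBEOperator(m, law_level, dofmap)
        B = op.rhs_from_bcs()
        monitor = stress_functional(op, bcs, m)

        u0 = None
        if u_prev_full is not None:
            ratio = prev_factor // f
            u0_full = prolong(u_prev_full, prev_model, m, ratio)
            u0 = dofmap.extract_free(u0_full)

        if finest:
            level_policy = policy
        else:
            level_policy = StoppingPolicy(
                mode="fixed-iterations",
                max_iterations=schedule.coarse_iterations,
                window=policy.window,
            )

        if finest and workers > 1:
            part = partition_z(dofmap, m, workers)
            u, trace = partitioned_pcg(op, B, u0, level_policy, part, monitor=monitor)
        else:
            u, trace = pcg_solve(op, B, u0, level_policy, monitor=monitor)
        iterations_per_level.append(trace.iterations)

        u_prev_full = dofmap.full_field(u)
        prev_model, prev_factor = m, f
        last = dict(op=op, bcs=bcs, model=m, trace=trace, full_u=u_prev_full)

    op, bcs, m, trace = last["op"], last["bcs"], last["model"], last["trace"]
    full_u = last["full_u"]
    stress = total_stress(op, full_u, bcs, m)
    stiffness = apparent_stiffness(stress, load.strain) if load.strain > 0 else 0.0
    emap = strain_energy_map(op, full_u, m) if compute_energy_map else None
    return SolveResult(
        displacements=full_u,
        stiffness=stiffness,
        stress=stress,
        strain=load.strain,
        iterations_per_level=iterations_per_level,
        converged=trace.converged,
        trace=trace,
        energy_map=emap,
        model=m,
    )
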