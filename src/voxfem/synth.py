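"""Synthetic structure generators.

Deterministic and seeded stand-ins for micro-CT / MR derived bone volumes:
solid blocks and layered composites with closed-form stiffness, periodic
plate/rod lattices emulating the interconnected plate-and-strut topology
of trabecular bone, thresholded smoothed-noise porous structures at a
target bone-volume fraction, and a surface-resorption "degrade" operator
for longitudinal / monotonicity experiments.  All generators are pure
functions of their arguments and seed, and (unless noted) produce
structures that span and anchor to the loaded faces.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .model import _VERTEX_CONNECTIVITY, VoxelModel

__all__ = [
    "solid_block",
    "layered_block",
    "plate_rod_lattice",
    "random_porous",
    "degrade",
]


def solid_block(dims: tuple[int, int, int], voxel_size: float = 1.0) -> VoxelModel:
    """Fully dense block, BVF = 1 everywhere."""
    return VoxelModel(bvf=np.ones(dims), voxel_size=voxel_size)


def layered_block(
    dims: tuple[int, int, int],
    fractions: tuple[float, ...],
    voxel_size: float = 1.0,
    axis: int = 2,
) -> VoxelModel:
    """Equal-thickness layers of constant BVF stacked along ``axis``.

    Layer boundaries fall on exact voxel planes, so the number of voxels
    along the axis must be divisible by the number of layers.  Two layers
    under frictionless axial compression give the series-spring
    (harmonic-mean) apparent stiffness in the decoupled (nu = 0) case.
    """
    n = dims[axis]
    if n % len(fractions):
        raise ValueError("axis length must be divisible by the number of layers")
    thickness = n // len(fractions)
    bvf = np.empty(dims)
    sel = [slice(None)] * 3
    for i, frac in enumerate(fractions):
        sel[axis] = slice(i * thickness, (i + 1) * thickness)
        bvf[tuple(sel)] = frac
    return VoxelModel(bvf=bvf, voxel_size=voxel_size)


def plate_rod_lattice(
    dims: tuple[int, int, int],
    spacing: int = 8,
    thickness: int = 3,
    voxel_size: float = 1.0,
) -> VoxelModel:
    """Periodic lattice of transverse plates connected by axial rods.

    A voxel is solid when it lies in a plate (``k % spacing < thickness``)
    or in a vertical rod (``i % spacing < thickness`` and
    ``j % spacing < thickness``).  The structure is a single connected
    component spanning the z faces; its exact solid-voxel count follows by
    inclusion-exclusion from the per-axis index counts.
    """
    if not (0 < thickness < spacing):
        raise ValueError("need 0 < thickness < spacing")
    i, j, k = np.ogrid[: dims[0], : dims[1], : dims[2]]
    plates = (k % spacing) < thickness
    rods = ((i % spacing) < thickness) & ((j % spacing) < thickness)
    bvf = (plates | rods).astype(float)
    return VoxelModel(bvf=bvf, voxel_size=voxel_size)


def _spanning_components(mask: np.ndarray, axis: int = 2) -> np.ndarray:
    """Labels of components touching both faces along ``axis``."""
    labels, n = ndimage.label(mask, structure=_VERTEX_CONNECTIVITY)
    if n == 0:
        return np.array([], dtype=int), labels
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis], hi[axis] = 0, mask.shape[axis] - 1
    lo_labels = np.unique(labels[tuple(lo)])
    hi_labels = np.unique(labels[tuple(hi)])
    spanning = np.intersect1d(lo_labels, hi_labels)
    return spanning[spanning > 0], labels


def random_porous(
    dims: tuple[int, int, int],
    target_bvf: float = 0.12,
    smoothing: float = 2.0,
    seed: int = 0,
    voxel_size: float = 1.0,
    axis: int = 2,
    tol: float = 0.01,
    column_bias: float = 1.0,
) -> VoxelModel:
    """Seeded porous structure at a target volume fraction.

    A Gaussian-smoothed white-noise field — with a weak bias of smooth
    columns along the load axis, emulating the preferred orientation of
    primary trabeculae — is thresholded by greedy connected growth: a thin
    spanning seed column is placed at the strongest column of the field
    and the structure grows by repeatedly annexing the highest-field
    voxels adjacent to it (vertex connectivity), until the target solid
    count is reached.  The result is a single connected component spanning
    both loaded faces whose BVF matches ``target_bvf`` to voxel
    granularity (always within ``tol``).  ``smoothing`` (voxels) sets the
    characteristic strut thickness.
    """
    if not (0 < target_bvf < 1):
        raise ValueError("target_bvf must be in (0, 1)")
    axes_order = [d for d in range(3) if d != axis] + [axis]  # load axis last
    work_dims = tuple(dims[a] for a in axes_order)
    nx, ny, nz = work_dims
    n_target = int(round(target_bvf * nx * ny * nz))
    if n_target < 2 * nz:
        raise ValueError("target_bvf too low for a spanning structure at these dims")

    rng = np.random.default_rng(seed)
    noise = ndimage.gaussian_filter(rng.standard_normal(work_dims), smoothing)
    noise /= noise.std()
    n_cols = max(3, int(round(nx * ny * 0.04)))
    bias2d = np.zeros((nx, ny))
    bias2d[rng.integers(0, nx, n_cols), rng.integers(0, ny, n_cols)] = 1.0
    bias2d = ndimage.gaussian_filter(bias2d, 1.5, mode="wrap")
    field = noise + column_bias * (bias2d / bias2d.max())[:, :, None]

    # spanning seed: a 2x2 column through the strongest column of the field
    cmean = field.mean(axis=2)
    ci, cj = np.unravel_index(np.argmax(cmean), cmean.shape)
    cluster = np.zeros(work_dims, dtype=bool)
    cluster[ci : min(ci + 2, nx), cj : min(cj + 2, ny), :] = True

    while cluster.sum() < n_target:
        frontier = ndimage.binary_dilation(cluster, structure=_VERTEX_CONNECTIVITY) & ~cluster
        k = min(n_target - int(cluster.sum()), int(frontier.sum()))
        if k == 0:
            raise ValueError("structure cannot grow further")
        vals = np.where(frontier, field, -np.inf)
        cluster |= vals >= np.partition(vals.ravel(), -k)[-k]

    achieved = cluster.mean()
    if abs(achieved - target_bvf) > tol:
        raise ValueError(
            f"could not reach target BVF {target_bvf:.3f} (achieved {achieved:.3f})"
        )
    bvf = np.transpose(cluster.astype(float), np.argsort(axes_order))
    return VoxelModel(bvf=bvf, voxel_size=voxel_size)


def degrade(model: VoxelModel, removal_fraction: float, seed: int = 0) -> VoxelModel:
    """Randomly resorb surface voxels, emulating trabecular bone loss.

    Removes ``removal_fraction`` of the surface voxels (active voxels with
    at least one inactive 6-neighbor or on the volume boundary).  Material
    only ever decreases, so apparent stiffness is non-increasing.
    """
    if not (0.0 <= removal_fraction <= 1.0):
        raise ValueError("removal_fraction must be in [0, 1]")
    if removal_fraction == 0.0:
        return model
    mask = model.bvf > 0
    interior = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    surface = np.argwhere(mask & ~interior)
    n_remove = int(round(removal_fraction * surface.shape[0]))
    if n_remove == 0:
        return model
    rng = np.random.default_rng(seed)
    chosen = surface[rng.choice(surface.shape[0], size=n_remove, replace=False)]
    bvf = model.bvf.copy()
    bvf[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = 0.0
    return VoxelModel(bvf=bvf, voxel_size=model.voxel_size)
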