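"""Preconditioned conjugate gradient solver with a stress-based stopping rule.

Three stopping modes are supported:

* ``estimated-error`` (default): assumes the monitored total stress S_n
  converges exponentially, ``S_n = S_inf + alpha * exp(b n)``, once the
  iteration enters its asymptotic regime.  A least-squares line fit of
  ``log |S_n - S_{n-1}|`` against n over a sliding window yields slope b
  and intercept a, from which the remaining relative error is modeled as
  ``exp(a + b n) / (|b| |S_n|)``.
* ``scaled-residual``: the conventional ``||r|| / ||B||`` criterion.
* ``fixed-iterations``: run an exact iteration count (used on coarse
  pre-iteration grids).

The partitioned variant executes the same iteration as a deterministic
schedule over contiguous Z-slab sub-regions: the operator is applied
per region on its inner vertices only, and inner products are reduced as
per-region partial sums combined in ascending region order, so the result
is independent of how many workers execute the regions.  With one region
it is bitwise identical to the serial path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import DofMap, VoxelModel
from .operator import EBEOperator

__all__ = [
    "DivergenceError",
    "StoppingPolicy",
    "ConvergenceTrace",
    "Partition",
    "pcg_solve",
    "partitioned_pcg",
    "partition_z",
    "estimate_relative_error",
    "scaled_residual",
]

#: Residual floor: below this scaled residual the iterate is converged to
#: round-off regardless of the stopping mode.
RESIDUAL_FLOOR = 1e-14


class DivergenceError(RuntimeError):
    """Raised when CG produces non-finite values."""


@dataclass(frozen=True)
class StoppingPolicy:
    """When to halt the conjugate gradient iteration.

    ``tolerance`` is a relative stress error for ``estimated-error`` mode
    (default 1%, the accuracy criterion used throughout), a scaled
    residual for ``scaled-residual`` mode, and ignored by
    ``fixed-iterations``.  ``window`` is the number of most recent
    iterations entering the log-derivative fit (default 30).
    """

    mode: str = "estimated-error"
    tolerance: float = 0.01
    window: int = 30
    max_iterations: int | None = None
    check_every: int = 1
    #: consecutive sub-tolerance estimated-error checks required before
    #: stopping; guards against a single spurious window fit
    patience: int = 3

    def __post_init__(self) -> None:
        if self.mode not in ("estimated-error", "scaled-residual", "fixed-iterations"):
            raise ValueError(f"unknown stopping mode {self.mode!r}")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")
        if self.window < 3:
            raise ValueError("window must be >= 3")
        if self.check_every < 1:
            raise ValueError("check_every must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    def resolve_max_iterations(self, n_free: int) -> int:
        if self.max_iterations is not None:
            return self.max_iterations
        return min(10000, int(10 * self.window * np.sqrt(max(n_free, 1))))


@dataclass
class ConvergenceTrace:
    """Per-iteration diagnostics of a CG run."""

    stress: list[float] = field(default_factory=list)  # S_n, MPa
    scaled_residuals: list[float] = field(default_factory=list)
    estimated_errors: list[float | None] = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)
    slope: float | None = None
    intercept: float | None = None
    iterations: int = 0
    converged: bool = False


def scaled_residual(r: np.ndarray, B: np.ndarray) -> float:
    """``||r||_2 / ||B||_2`` — residual relative to the imposed boundary force."""
    nb = float(np.linalg.norm(B))
    if nb == 0.0:
        raise ValueError("scaled residual undefined: ||B|| = 0")
    return float(np.linalg.norm(r)) / nb


def estimate_relative_error(
    stress: Sequence[float], window: int = 30
) -> tuple[float, float, float] | None:
    """Exponential-fit estimate of the remaining relative stress error.

    Fits ``log D_n`` (``D_n = |S_n - S_{n-1}|``, finite differences as the
    derivative estimate) against n over the last ``window`` differences.
    Under ``S_n = S_inf + alpha exp(b n)`` the remaining error is
    ``|S_n - S_inf| = exp(a + b n)/|b|``.

    Returns ``(relative_error, slope, intercept)`` or ``None`` when no
    valid estimate exists (too few points, all-zero differences, or a
    non-negative fitted slope).
    """
    s = np.asarray(stress, dtype=float)
    if s.size < window + 1:
        return None
    n_last = s.size - 1
    ns = np.arange(n_last - window + 1, n_last + 1)
    D = np.abs(s[ns] - s[ns - 1])
    ok = D > 0
    if ok.sum() < 3:
        return None
    b, a = np.polyfit(ns[ok], np.log(D[ok]), 1)
    if not np.isfinite(b) or b >= 0:
        return None
    s_now = abs(s[n_last])
    if s_now == 0:
        return None
    err = float(np.exp(a + b * n_last) / (abs(b) * s_now))
    return err, float(b), float(a)


# ---------------------------------------------------------------------------
# Z-slab partitioning


@dataclass(frozen=True)
class Region:
    """One contiguous Z-slab sub-region.

    ``z_lo:z_hi`` is the half-open range of *inner* vertex layers;
    ``inner`` are the free-variable ids owned by the region (ascending),
    ``outer`` the duplicated interface ids read from neighbors, and
    ``elements`` the indices (into the operator's element list) of all
    elements touching an inner vertex.
    """

    z_lo: int
    z_hi: int
    inner: np.ndarray
    outer: np.ndarray
    elements: np.ndarray


@dataclass(frozen=True)
class Partition:
    regions: tuple[Region, ...]

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def partition_z(dofmap: DofMap, model: VoxelModel, K: int) -> Partition:
    """Split the free variables into K load-balanced contiguous Z slabs.

    Cut planes are placed at cumulative quantiles of the per-layer free
    variable counts, so each slab's inner count is within one vertex
    layer's worth of ``N_v / K``.
    """
    nz_vert = model.dims[2] + 1
    if not (1 <= K <= model.dims[2]):
        raise ValueError("number of regions must satisfy 1 <= K <= N_z")

    free = dofmap.var_id >= 0
    per_layer = free.sum(axis=(0, 1, 3))  # free dofs per vertex z-layer
    cum = np.cumsum(per_layer)
    total = cum[-1]
    # cut after the layer where the cumulative count first reaches k/K
    cuts = [0]
    for k in range(1, K):
        target = total * k / K
        z = int(np.searchsorted(cum, target)) + 1
        cuts.append(max(cuts[-1] + 1, min(z, nz_vert - (K - k))))
    cuts.append(nz_vert)

    # map each free id to its vertex z-layer
    z_of_id = np.empty(dofmap.n_free, dtype=np.int64)
    ids = dofmap.var_id[free]
    z_idx = np.broadcast_to(
        np.arange(nz_vert)[None, None, :, None], dofmap.var_id.shape
    )[free]
    z_of_id[ids] = z_idx

    elem_z = dofmap.elements[:, 2]  # element spans vertex layers z..z+1
    regions = []
    for k in range(K):
        z_lo, z_hi = cuts[k], cuts[k + 1]
        inner = np.flatnonzero((z_of_id >= z_lo) & (z_of_id < z_hi))
        neighbor_layers = []
        if z_lo > 0:
            neighbor_layers.append(z_lo - 1)
        if z_hi < nz_vert:
            neighbor_layers.append(z_hi)
        outer = (
            np.flatnonzero(np.isin(z_of_id, neighbor_layers))
            if neighbor_layers
            else np.array([], dtype=np.int64)
        )
        elems = np.flatnonzero((elem_z + 1 >= z_lo) & (elem_z < z_hi))
        regions.append(
            Region(z_lo=z_lo, z_hi=z_hi, inner=inner, outer=outer, elements=elems)
        )
    return Partition(regions=tuple(regions))


# ---------------------------------------------------------------------------
# PCG core

Monitor = Callable[[int, np.ndarray], float]


def _region_apply(op: EBEOperator, p: np.ndarray, region: Region) -> np.ndarray:
    """A @ p restricted to the inner vertices of one region."""
    ue = np.append(p, 0.0)[op._gather[region.elements]]
    fe = (ue @ op.kernel) * op.moduli[region.elements, None]
    out = np.bincount(
        op._gather[region.elements].ravel(), weights=fe.ravel(), minlength=op.n_free + 1
    )
    return out[: op.n_free]


def _pcg(
    op: EBEOperator,
    B: np.ndarray,
    u0: np.ndarray | None,
    policy: StoppingPolicy,
    monitor: Monitor | None,
    partition: Partition | None,
) -> tuple[np.ndarray, ConvergenceTrace]:
    n = op.n_free
    trace = ConvergenceTrace()
    u = np.zeros(n) if u0 is None else np.array(u0, dtype=float)
    if u.shape != (n,):
        raise ValueError("initial displacement vector has wrong length")

    precond = op.jacobi_diagonal()
    max_iter = policy.resolve_max_iterations(n)
    norm_b = float(np.linalg.norm(B))
    if norm_b == 0.0:
        trace.converged = True
        return u, trace

    serial = partition is None or partition.n_regions == 1
    regions = None if serial else partition.regions

    def apply_A(p: np.ndarray) -> np.ndarray:
        if serial:
            return op.apply(p)
        q = np.zeros(n)
        for reg in regions:  # Step 1a per sub-region, inner vertices only
            q_r = _region_apply(op, p, reg)
            q[reg.inner] = q_r[reg.inner]
        return q

    def dot(a: np.ndarray, b: np.ndarray) -> float:
        if serial:
            return float(a @ b)
        # Steps 1b/2: partial sums over inner ids, ascending region order
        return float(np.sum([a[reg.inner] @ b[reg.inner] for reg in regions]))

    r = B - apply_A(u)
    z = precond.apply(r)
    p = z.copy()
    rz = dot(r, z)
    below_tol_streak = 0

    def record(it: int, res_norm: float) -> None:
        trace.iterations = it
        trace.scaled_residuals.append(res_norm / norm_b)
        if monitor is not None:
            trace.stress.append(float(monitor(it, u)))
        est = None
        if (
            policy.mode == "estimated-error"
            and monitor is not None
            and it >= policy.window + 5
            and it % policy.check_every == 0
        ):
            fit = estimate_relative_error(trace.stress, policy.window)
            if fit is not None:
                est, trace.slope, trace.intercept = fit
        trace.estimated_errors.append(est)

    record(0, float(np.linalg.norm(r)))
    if trace.scaled_residuals[-1] < RESIDUAL_FLOOR:
        trace.converged = True
        return u, trace

    for it in range(1, max_iter + 1):
        q = apply_A(p)
        pq = dot(p, q)
        if not np.isfinite(pq) or pq <= 0:
            if pq == 0:
                raise DivergenceError("search direction with zero curvature")
            raise DivergenceError("non-finite or negative curvature in CG")
        alpha = rz / pq
        u += alpha * p
        r -= alpha * q
        z = precond.apply(r)
        rz_new = dot(r, z)
        beta = rz_new / rz
        p = z + beta * p
        rz = rz_new
        trace.alphas.append(float(alpha))

        res_norm = float(np.linalg.norm(r))
        if not np.isfinite(res_norm):
            raise DivergenceError("non-finite residual in CG")
        record(it, res_norm)

        sres = trace.scaled_residuals[-1]
        if sres < RESIDUAL_FLOOR:
            trace.converged = True
            break
        if policy.mode == "scaled-residual" and sres <= policy.tolerance:
            trace.converged = True
            break
        if policy.mode == "estimated-error":
            est = trace.estimated_errors[-1]
            if est is not None:
                below_tol_streak = below_tol_streak + 1 if est <= policy.tolerance else 0
                if below_tol_streak >= policy.patience:
                    trace.converged = True
                    break
    else:
        trace.converged = policy.mode == "fixed-iterations"
    if policy.mode == "fixed-iterations" and trace.iterations >= max_iter:
        trace.converged = True
    return u, trace


def pcg_solve(
    op: EBEOperator,
    B: np.ndarray,
    u0: np.ndarray | None = None,
    policy: StoppingPolicy | None = None,
    monitor: Monitor | None = None,
) -> tuple[np.ndarray, ConvergenceTrace]:
    """Jacobi-preconditioned conjugate gradients on the free variables.

    ``monitor(iteration, u)`` is called once per iteration and must return
    the monitored total stress S_n; it is required for the default
    ``estimated-error`` stopping mode.
    """
    policy = policy or StoppingPolicy()
    if policy.mode == "estimated-error" and monitor is None:
        raise ValueError("estimated-error stopping requires a stress monitor")
    return _pcg(op, B, u0, policy, monitor, partition=None)


def partitioned_pcg(
    op: EBEOperator,
    B: np.ndarray,
    u0: np.ndarray | None = None,
    policy: StoppingPolicy | None = None,
    partition: Partition | None = None,
    monitor: Monitor | None = None,
) -> tuple[np.ndarray, ConvergenceTrace]:
    """PCG executed under the sub-region partition contract.

    Iterates are identical to the serial solver up to summation-order
    round-off (bitwise identical for a single region).  Concurrency is an
    execution hint: correctness never depends on worker scheduling because
    reductions are ordered by region index.
    """
    if partition is None:
        raise ValueError("partitioned_pcg requires a partition")
    inner_all = np.concatenate([r.inner for r in partition.regions])
    if inner_all.size != op.n_free or np.unique(inner_all).size != op.n_free:
        raise ValueError("partition inner sets do not partition the free variables")
    policy = policy or StoppingPolicy()
    if policy.mode == "estimated-error" and monitor is None:
        raise ValueError("estimated-error stopping requires a stress monitor")
    return _pcg(op, B, u0, policy, monitor, partition=partition)
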