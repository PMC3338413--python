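# Methods

## Model

voxfem performs linear-elastic micro-finite-element (μFE) analysis of 3D
bone images under the one-voxel-one-element convention: every voxel of a
bone-volume-fraction (BVF) image becomes an 8-node hexahedral (brick)
element with tri-linear displacement interpolation.  Local stress and
strain are related by isotropic Hooke's law in Voigt notation
(order xx, yy, zz, yz, xz, xy, engineering shear strains).  The element's
Young's modulus is

* grayscale mode (default): `E_elem = E_tissue * BVF`, appropriate for
  partial-volume images (in-vivo MR/CT);
* binary mode: `E_tissue` where `BVF >= threshold` (default 0.5), else
  inactive, appropriate for segmented micro-CT.

Voxel-wise isotropy is assumed throughout; tissue-level anisotropy is not
modeled.  Defaults are `E_tissue = 15000 MPa` and `nu = 0.3`, the common
convention for trabecular-bone μFE; both are configurable, and all
reported stiffnesses scale linearly with `E_tissue`.

Because the element is a cube, a single 24x24 unit-modulus stiffness
kernel `K = ∫ Bᵀ C B dV` serves every element up to the scalar modulus.
It is evaluated by 2x2x2 Gauss quadrature, which is exact for this
polynomial integrand (verified against a 4x4x4 rule to 1e-10); the kernel
scales linearly with edge length and is cached per (nu, edge).  Its null
space is exactly the six rigid-body modes.  Anisotropic voxel spacing is
rejected rather than resampled, since the kernel derivation assumes a
cube.

## Linear system and matrix-free solver

A simulated compression test prescribes displacements on the two faces
perpendicular to the load axis (bottom fixed axially, top displaced by
`-strain * length`; transverse directions free by default, or clamped).
Force equilibrium at all free (vertex, direction) pairs yields a linear
system `A U = B` in the `N_v` free variables, with `A` symmetric and
positive definite on anchored structures.  With frictionless
("axial-only") ends the in-plane rigid modes remain unconstrained, so `A`
is positive semi-definite; the right-hand side is orthogonal to that null
space, and conjugate gradients started from a vector in the range of `A`
converge to the minimum-norm solution, leaving the stress unaffected.
Connected components of elements (vertex-sharing, i.e. 26-connectivity)
that contain no constrained vertex would make the system singular and are
pruned before numbering.

`A` is never assembled.  The element-by-element (EBE) operator gathers
each element's 24 local displacements, multiplies by the modulus-scaled
kernel and scatter-adds into the free variables, in fixed element raster
order so serial results are reproducible bit-for-bit.  Free variables are
numbered in raster order over vertices with direction innermost, which is
what allows the production storage scheme to keep only 4 of the 24
per-element variable indices.  Solver vectors are double precision; the
analytic memory model (below) uses the 4-byte production accounting.

The solver is Jacobi-preconditioned conjugate gradients.  The
preconditioner is the inverse of the assembled diagonal; a non-positive
diagonal entry indicates an unpruned floating dof and raises.  An
explicit scipy.sparse assembly exists solely as a small-instance
verification oracle and is never on the solve path.

## Stress-based convergence estimation

The clinically relevant output is the total stress — the sum of axial
reaction forces on the displaced face divided by the full cross-sectional
area (apparent stress, compression positive) — rather than the residual
norm.  Since reactions are linear in the displacements, the monitored
stress is precomputed as an affine functional `S(u) = g·u + s0`, making
per-iteration monitoring one dot product.

Assuming `S_n = S_inf + alpha * exp(b n)` in the asymptotic regime, the
log of the absolute finite difference `D_n = |S_n − S_{n−1}|` is linear
in `n`; a least-squares fit over the last 30 iterations (window
configurable) gives slope `b` and intercept `a`, and the remaining
relative error is estimated as `exp(a + b n) / (|b| |S_n|)`.  Zero
differences are dropped from the window; a non-negative fitted slope
returns "estimate unavailable" and iteration continues.  Estimates are
only computed after `window + 5` iterations, and stopping requires the
estimate to sit below tolerance on 3 consecutive checks (`patience`),
which guards against a single noisy window fit.  The default tolerance is
1% estimated stress error.  Two alternative stopping modes exist: the
conventional scaled residual `‖r‖/‖B‖`, and a fixed iteration count (used
on coarse pre-iteration grids).  A scaled residual below 1e-14 always
terminates, covering warm starts that are already converged.

On desk-scale fixtures (tens of thousands of variables) CG convergence is
partly superlinear, so the windowed exponential fit is conservative early
in the run and most accurate near the stopping crossing; the measured
guarantee (acceptance suite) is that stopping at an estimated 1% leaves a
true stress error below 2% — the factor-of-two accuracy of the estimator
in the direction that matters — with the true error taken against a
reference solve at scaled residual 1e-12.  Past the stopping point the
increments reach the round-off floor of the monitored series and the fit
ceases to be meaningful; no stopping decision depends on that regime.

## Partitioned execution

For load-balanced parallel iteration the free variables are split into K
contiguous Z-slab sub-regions, cut at cumulative quantiles of the
per-layer free-variable counts (balanced to within one vertex layer's
worth).  Interface vertex layers are duplicated, giving the
`2(K−1)/N_z` memory overhead fraction of the resource model.  Each
iteration applies the operator per region restricted to its inner
vertices, computes partial inner products over the inner index sets, and
reduces them in ascending region order (and ascending variable index
within regions), so results are independent of worker scheduling; with
one region the path is bitwise identical to the serial solver.  The
worker count is an execution hint, never a correctness parameter — the
implementation executes the partitioned schedule deterministically, and
iterates agree with the serial solver to summation-order round-off
(per-iteration step sizes to 1e-12 relative, final stiffness to 1e-8, as
tested).

## Pre-iteration on coarser grids

The model hierarchy is built by block-mean downsampling (factor f, grids
zero-padded to a multiple of f; padding adds only inactive material).
Block means preserve total bone volume, and coarse levels always use
grayscale material scaling since averaging produces fractional BVF.
Boundary conditions are regenerated at each level for the same
macroscopic strain, so the prescribed physical displacement matches
across levels.  The default schedule is 4-2-1 with a fixed 200 iterations
per coarse level; the finest level runs under the ordinary stopping
policy, warm-started by tri-linear interpolation of the coarse
displacement field at the fine vertex positions (displacements are
physical, so no rescaling; interpolation is exact on affine fields and
copies coarse values at coincident vertices).  This is a warm-start
scheme, not multigrid: no residual restriction or V-cycles.

## Resource models

Pure arithmetic, never measurement.  Per element the EBE scheme stores
1 byte of BVF, 16 bytes of compressed variable indices (24 x 4 bytes, of
which one sixth need storing), 4 x 5 bytes per variable for the five CG
vectors plus preconditioner (~80 B/element at the empirical
`N_v ≈ 4 N_e`), and a 4-byte-per-vertex lookup map (bounded by 32
B/element at ≥1/8 occupancy, or computed from actual dims) — ~130
B/element, times the partition duplication overhead.  Explicit sparse
storage needs up to 81 entries x 4 bytes = 324 B/variable = 1296
B/element, a factor of ~10 more; per iteration EBE performs 24² multiplies
per element versus up to 81 per variable for a sparse product, a ratio of
1.8.  Rounding conventions (totals to the nearest ten bytes, the ratio to
one decimal) are fixed so the printed figures are deterministic.

## Synthetic structures

The generators replace image inputs and are pure functions of their
parameters and seed:

* `solid_block`, `layered_block` — closed-form validation targets.  A
  solid block under frictionless compression carries uniform uniaxial
  strain, which lies exactly in the tri-linear space, so the computed
  apparent stiffness equals the tissue modulus to solver tolerance.  Two
  equal layers of moduli E1, E2 behave as springs in series,
  `2 E1 E2/(E1+E2)`; this closed form is exact only when the lateral
  Poisson contraction matches across the interface, hence the nu = 0
  validation case.  With nu = 0.3 a Saint-Venant boundary layer at the
  interface shifts the apparent stiffness by ~0.5% on an 8³ block — a
  real elasticity effect, not discretization error.
* `plate_rod_lattice` — periodic transverse plates connected by axial
  rods; exact solid count by inclusion–exclusion, single connected
  component, spans the loaded faces.  Strut thickness 3 voxels at spacing
  8 by default, matching trabecular dimensions (~100–150 µm) at micro-CT
  voxel sizes, and giving the empirical `N_v/N_e` ratio in the 3–4.5
  range typical of trabecular models.
* `random_porous` — Gaussian-smoothed white noise (smoothing 2.0 voxels,
  i.e. strut scale ~4 voxels) plus a weak smooth column bias along the
  load axis that emulates the preferred orientation of primary
  trabeculae.  Isotropic blob noise percolates only above ~15–17% volume
  fraction at these grid sizes, unlike real trabecular bone, which
  remains connected at 10% BVF precisely because it is oriented; the bias
  restores that behavior.  The structure is produced by greedy connected
  growth: a thin spanning seed column at the strongest column of the
  field, then repeated annexation of the highest-field frontier voxels
  (vertex connectivity) until the target solid count is reached, which
  hits the requested BVF to voxel granularity and guarantees a single
  anchored spanning component.  Default benchmark fixture: 32³ at target
  BVF 0.12 (the 10–15% range typical of distal-site trabecular bone).
* `degrade` — removes a fraction of surface voxels (active voxels with an
  inactive 6-neighbor or on the boundary) uniformly at random, emulating
  resorption for longitudinal and monotonicity experiments.

What these fixtures do not capture: real trabecular morphometry (plate
thickness distributions, anisotropy tensors, marrow-space geometry),
image noise and partial-volume blur, and the scale of clinical data
(10⁶–10⁸ elements versus ~10⁴ here).  Passing tests therefore validate
the numerics — kernel, operator, solver, estimator, schedules — at desk
scale, not image-processing fidelity or large-scale performance.

## Problem sizes and numerical choices

The test and acceptance suites run solid/layered blocks at 16³, oracle
comparisons on 4³ random structures against explicit assembly and direct
sparse solves, partition checks on a 24³ lattice, and estimator/PICG/
monotonicity sweeps on 20³–32³ seeded porous fixtures — sizes chosen so
every dual-route check (matrix-free vs assembled, iterative vs direct,
serial vs partitioned, fine vs warm-started) completes in seconds while
exercising the same code paths as large runs.  Key tolerances: operator
vs assembly 1e-10 relative; PCG vs direct solve 1e-8; partition
independence 1e-8; closed-form stiffness 0.1%; estimator stopping
guarantee 2% true error at 1% estimated.  Degenerate inputs (empty
models, unanchored structures, zero strain, zero right-hand side,
non-spanning structures, anisotropic spacing) raise informative errors
rather than returning silently wrong results.

## Known limitations

Linear elasticity only (no damage, yield or failure-load estimation);
single uniaxial load case (no shear/torsion or full homogenized stiffness
tensors); Jacobi is the only preconditioner; partitioned execution is a
deterministic contract rather than actual multithreading; apparent
stiffness normalizes by the full image cross-section (total-area
convention, documented in the report output).
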