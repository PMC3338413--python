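# voxfem

Matrix-free voxel micro-finite-element (μFE) analysis of trabecular bone
images on ordinary desktops.

High-resolution MR and CT images of trabecular bone can be turned into
mechanical estimates — apparent stiffness, strain-energy maps — by
letting every image voxel become one hexahedral finite element.  The
resulting linear systems reach 10⁷–10⁸ unknowns, historically
supercomputer territory.  voxfem implements the algorithmic package that
makes such models tractable on a workstation:

* **Element-by-element (EBE) operator** — the global stiffness matrix
  `A` is never assembled; one shared 24×24 unit-modulus kernel (scaled by
  each element's BVF-derived modulus) is applied element-wise,
  cutting memory from ~1296 to ~130 bytes per element (~10×) at the cost
  of ~1.8× more multiplications per iteration.
* **Jacobi-preconditioned conjugate gradients** with a stress-based
  stopping rule: assuming the monitored total stress converges
  exponentially, a line fit to `log |S_n − S_{n−1}|` over the last 30
  iterations extrapolates the remaining relative error — stopping when
  the *quantity of interest* is converged, not when the residual happens
  to be small.
* **Pre-iteration on coarser grids (PICG)** — solve block-mean
  downsampled models first (default schedule 4-2-1, 200 iterations per
  coarse level) and tri-linearly interpolate displacements as warm
  starts, roughly halving fine-grid iterations.
* **Load-balanced Z-slab partitioning** with a deterministic reduction
  contract: results are independent of the number of sub-regions to
  round-off (memory overhead `2(K−1)/N_z`).
* **Analytic resource models** for memory and multiplication counts, and
  **synthetic structure generators** (solid/layered blocks, plate-rod
  lattices, seeded trabecular-like porous networks, surface resorption)
  so every solver path is exercised without any image data.

Apparent axial stiffness is the macroscopic stress/strain ratio
`S/ε` (MPa) of a simulated uniaxial compression test: bottom face fixed
axially, top face displaced by `−ε·L`, total reaction force on the
displaced face divided by the full cross-section.

## Worked example

```python
import voxfem as vf

model = vf.random_porous((32, 32, 32), target_bvf=0.12, seed=3, voxel_size=0.15)
law = vf.MaterialLaw(tissue_modulus=15000.0, poisson_ratio=0.3)   # MPa
load = vf.UniaxialCompression(strain=0.01)                        # 1% compression

result = vf.picg_solve(model, law, load,
                       schedule=vf.GridSchedule((4, 2, 1)),
                       policy=vf.StoppingPolicy(tolerance=0.01))
print(round(result.stiffness, 1), result.iterations_per_level)
```

prints

```
1713.5 [98, 178, 37]
```

a trabecular-like structure at 12% bone volume fraction with an apparent
stiffness of ~1.7 GPa — about 11% of the tissue modulus, the expected
order for trabecular bone — reached with only 37 fine-grid iterations
after the coarse warm starts (52 are needed without them; both routes
agree to 0.03%).  The same pipeline is available from the shell:

```bash
voxfem synth porous vol.nii --dims 32,32,32 --seed 3
voxfem run vol.nii --strain 0.01 --schedule 4,2,1 --report report.txt
voxfem estimate --elements 75e6 --threads 8 --nz 1770
```

The `examples/` directory contains short narrative scripts, one per
capability (compression test, memory budget, coarse-grid warm starts,
convergence estimation, longitudinal degradation).

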