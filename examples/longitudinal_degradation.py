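"""Stiffness loss under simulated trabecular resorption.

Emulates a longitudinal study: surface voxels of a porous structure are
randomly resorbed and the apparent stiffness is recomputed.  Removing
material can only soften the structure, but the mechanical impact is
disproportionate to the bone volume lost — thin load-bearing struts are
severed, which is exactly why image-derived stiffness is a more sensitive
marker than bone volume fraction alone.
"""

import voxfem as vf

law = vf.MaterialLaw()
load = vf.UniaxialCompression(strain=0.01)
policy = vf.StoppingPolicy(mode="scaled-residual", tolerance=1e-9)

model = vf.random_porous((24, 24, 24), target_bvf=0.15, seed=5)
s0 = vf.picg_solve(model, law, load, vf.GridSchedule((1,)), policy).stiffness
bv0 = model.bvf.sum()
print(f"baseline: BVF {model.bvf.mean():.3f}, stiffness {s0:.1f} MPa")

for frac in (0.05, 0.10, 0.20):
    degraded = vf.degrade(model, frac, seed=99)
    s = vf.picg_solve(degraded, law, load, vf.GridSchedule((1,)), policy).stiffness
    bone_loss = 100 * (1 - degraded.bvf.sum() / bv0)
    stiff_loss = 100 * (1 - s / s0)
    print(f"resorb {frac:.0%} of surface: bone -{bone_loss:4.1f}%, "
          f"stiffness -{stiff_loss:4.1f}%  ({s:.1f} MPa)")

# The percentage stiffness loss exceeds the percentage bone loss:
# mechanical competence degrades faster than bone mass.
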