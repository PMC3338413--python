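import numpy as np
import pytest

import voxfem as vf
from voxfem.mechanics import stress_functional


@pytest.fixture
def law():
    return vf.MaterialLaw()


@pytest.fixture
def load():
    return vf.UniaxialCompression(strain=0.01)


def build_system(model, law, load):
    """Prune, number dofs and build the operator + RHS + stress monitor."""
    bcs = load.bcs(model, law)
    model = vf.prune_unanchored(model, law, bcs)
    dofmap = vf.build_dof_map(model, law, bcs)
    op = vf.EBEOperator(model, law, dofmap)
    B = op.rhs_from_bcs()
    monitor = stress_functional(op, bcs, model)
    return model, bcs, dofmap, op, B, monitor


def random_grayscale_model(dims, seed, voxel_size=1.0, low=0.05):
    """Fully active random-BVF block (anchored for any face loading)."""
    rng = np.random.default_rng(seed)
    bvf = rng.uniform(low, 1.0, size=dims)
    return vf.VoxelModel(bvf=bvf, voxel_size=voxel_size)


def solve_tight(model, law, load, tol=1e-10):
    """Reference solve to a tight scaled residual; returns SolveResult."""
    policy = vf.StoppingPolicy(mode="scaled-residual", tolerance=tol, max_iterations=20000)
    return vf.picg_solve(model, law, load, vf.GridSchedule((1,)), policy)
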