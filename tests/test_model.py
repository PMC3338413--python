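import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import voxfem as vf
from voxfem.model import active_mask


def _compression_bcs(model, law, strain=0.01):
    return vf.uniaxial_compression_bcs(model, law, strain)


class TestVoxelModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            vf.VoxelModel(bvf=np.full((2, 2, 2), 1.5))
        with pytest.raises(ValueError):
            vf.VoxelModel(bvf=np.ones((2, 2)))
        with pytest.raises(ValueError):
            vf.VoxelModel(bvf=np.ones((2, 2, 2)), voxel_size=0.0)

    def test_physical_length(self):
        m = vf.VoxelModel(bvf=np.ones((2, 3, 4)), voxel_size=0.5)
        assert m.physical_length(2) == pytest.approx(2.0)


class TestMaterialLaw:
    @pytest.mark.parametrize(
        "bvf,mode,expected",
        [
            (0.0, "grayscale", 0.0),
            (1.0, "grayscale", 15000.0),
            (0.25, "grayscale", 3750.0),
            (0.49, "binary", 0.0),
            (0.5, "binary", 15000.0),
        ],
    )
    def test_element_modulus(self, bvf, mode, expected):
        m = vf.VoxelModel(bvf=np.full((1, 1, 1), bvf))
        law = vf.MaterialLaw(mode=mode)
        assert vf.element_modulus(m, law, (0, 0, 0)) == pytest.approx(expected)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            vf.MaterialLaw(poisson_ratio=0.5)
        with pytest.raises(ValueError):
            vf.MaterialLaw(tissue_modulus=0.0)
        with pytest.raises(ValueError):
            vf.MaterialLaw(mode="other")


class TestActiveElements:
    def test_solid_block_all_active(self, law):
        m = vf.solid_block((2, 2, 2))
        assert vf.active_elements(m, law).shape == (8, 3)

    def test_empty_model_raises(self, law):
        m = vf.VoxelModel(bvf=np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="no material"):
            vf.active_elements(m, law)

    def test_checkerboard_count_matches_enumeration(self, law):
        i, j, k = np.indices((4, 4, 4))
        bvf = ((i + j + k) % 2).astype(float)
        m = vf.VoxelModel(bvf=bvf)
        # independent enumeration oracle
        expected = sum(
            1 for a in range(4) for b in range(4) for c in range(4) if (a + b + c) % 2
        )
        assert expected == 32
        assert vf.active_elements(m, law).shape[0] == expected


class TestPruneUnanchored:
    def test_connected_block_unchanged(self, law):
        m = vf.solid_block((3, 3, 3))
        bcs = _compression_bcs(m, law)
        out = vf.prune_unanchored(m, law, bcs)
        np.testing.assert_array_equal(out.bvf, m.bvf)

    def test_floating_fragment_removed(self, law):
        bvf = np.zeros((8, 8, 8))
        bvf[:3, :3, :] = 1.0  # column spanning the z faces
        bvf[5:7, 5:7, 3:5] = 1.0  # floating cube
        m = vf.VoxelModel(bvf=bvf)
        bcs = _compression_bcs(m, law)
        out = vf.prune_unanchored(m, law, bcs)
        assert out.bvf[5:7, 5:7, 3:5].sum() == 0
        assert out.bvf[:3, :3, :].sum() == m.bvf[:3, :3, :].sum()

    def test_two_anchored_components_kept(self, law):
        bvf = np.zeros((8, 8, 4))
        bvf[:2, :2, :] = 1.0
        bvf[6:, 6:, :] = 1.0  # disjoint, but also spans the loaded faces
        m = vf.VoxelModel(bvf=bvf)
        out = vf.prune_unanchored(m, law, _compression_bcs(m, law))
        np.testing.assert_array_equal(out.bvf, m.bvf)

    def test_idempotent(self, law):
        bvf = np.zeros((8, 8, 8))
        bvf[:3, :3, :] = 1.0
        bvf[5:7, 5:7, 3:5] = 1.0
        m = vf.VoxelModel(bvf=bvf)
        bcs = _compression_bcs(m, law)
        once = vf.prune_unanchored(m, law, bcs)
        twice = vf.prune_unanchored(once, law, bcs)
        np.testing.assert_array_equal(once.bvf, twice.bvf)

    def test_nothing_anchored_raises(self, law):
        bvf = np.zeros((4, 4, 6))
        bvf[1:3, 1:3, 2:4] = 1.0  # touches neither z face
        m = vf.VoxelModel(bvf=bvf)
        bcs = vf.BoundarySpec(
            vertices=np.array([[0, 0, 0]]), directions=[2], values=[0.0]
        )
        with pytest.raises(ValueError, match="not anchored"):
            vf.prune_unanchored(m, law, bcs)


class TestDofMap:
    def test_single_unconstrained_element_has_24_free(self, law):
        m = vf.solid_block((1, 1, 1))
        bcs = vf.BoundarySpec(
            vertices=np.array([[0, 0, 0]]), directions=[2], values=[0.0]
        )
        dm = vf.build_dof_map(m, law, bcs)
        assert dm.n_free == 24 - 1

    def test_fully_constrained_faces_count(self, law):
        # 2x2x2 block, both z faces clamped in all directions:
        # 81 total dofs - 2 faces x 9 vertices x 3 directions = 27 free
        m = vf.solid_block((2, 2, 2))
        load = vf.UniaxialCompression(strain=0.01, end_condition="clamped")
        dm = vf.build_dof_map(m, law, load.bcs(m, law))
        assert dm.n_free == 27
        assert dm.n_elements == 8

    def test_solid_dof_conservation(self, law, load):
        m = vf.solid_block((3, 4, 5))
        bcs = load.bcs(m, law)
        dm = vf.build_dof_map(m, law, bcs)
        assert dm.n_free + int(dm.constrained.sum()) == 3 * 4 * 5 * 6

    def test_roundtrip_lookup(self, law, load):
        m = vf.plate_rod_lattice((16, 16, 16))
        dm = vf.build_dof_map(m, law, load.bcs(m, law))
        for vid in np.linspace(0, dm.n_free - 1, 50, dtype=int):
            i, j, k, d = dm.lookup(int(vid))
            assert dm.variable_index(i, j, k, d) == vid

    def test_raster_ordering_direction_innermost(self, law):
        m = vf.solid_block((2, 2, 2))
        bcs = vf.BoundarySpec(
            vertices=np.array([[0, 0, 0]]), directions=[0], values=[0.0]
        )
        dm = vf.build_dof_map(m, law, bcs)
        # first free dofs are directions 1, 2 of vertex (0,0,0), then x+1
        assert dm.lookup(0) == (0, 0, 0, 1)
        assert dm.lookup(1) == (0, 0, 0, 2)
        assert dm.lookup(2) == (1, 0, 0, 0)

    def test_trabecular_fixture_dof_ratio(self, law, load):
        """Free-variable count ~4x elements on plate/strut networks."""
        for spacing, thickness in ((8, 3), (6, 3), (8, 4)):
            m = vf.plate_rod_lattice((24, 24, 24), spacing, thickness)
            dm = vf.build_dof_map(m, law, load.bcs(m, law))
            assert 3.0 <= dm.n_free / dm.n_elements <= 4.5

    def test_full_field_embeds_prescribed(self, law, load):
        m = vf.solid_block((2, 2, 2), voxel_size=0.5)
        _bcs = load.bcs(m, law)
        dm = vf.build_dof_map(m, law, _bcs)
        full = dm.full_field(np.zeros(dm.n_free))
        assert full[0, 0, 2, 2] == pytest.approx(-0.01 * 1.0)
        assert full[0, 0, 0, 2] == 0.0


@settings(max_examples=20, deadline=None)
@given(
    dims=st.tuples(*(st.integers(1, 4),) * 3),
    seed=st.integers(0, 2**31 - 1),
)
def test_dofmap_roundtrip_property(dims, seed):
    """Reverse lookup inverts variable numbering on random occupancy."""
    rng = np.random.default_rng(seed)
    bvf = (rng.random(dims) > 0.4).astype(float)
    if bvf.sum() == 0:
        bvf[0, 0, 0] = 1.0
    m = vf.VoxelModel(bvf=bvf)
    law = vf.MaterialLaw()
    first = np.argwhere(active_mask(m, law))[0]
    bcs = vf.BoundarySpec(vertices=first[None, :], directions=[0], values=[0.0])
    dm = vf.build_dof_map(m, law, bcs)
    for vid in range(0, dm.n_free, max(1, dm.n_free // 17)):
        assert dm.variable_index(*dm.lookup(vid)) == vid
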