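import numpy as np
import pytest
import scipy.sparse.linalg as spla

import voxfem as vf
from voxfem.operator import PreconditionerDiag
from voxfem.solver import estimate_relative_error

from conftest import build_system, random_grayscale_model


class MatrixOperator:
    """Duck-typed stand-in exposing the operator surface PCG needs."""

    def __init__(self, A):
        self.A = np.asarray(A, dtype=float)
        self.n_free = self.A.shape[0]

    def apply(self, u):
        return self.A @ u

    def jacobi_diagonal(self):
        return PreconditionerDiag(inv_diag=1.0 / np.diag(self.A))


class TestPcgSolve:
    def test_two_by_two_hand_solved_system(self):
        """[[4,1],[1,3]] x = [1,2] has solution [1/11, 7/11] (elimination)."""
        op = MatrixOperator([[4.0, 1.0], [1.0, 3.0]])
        policy = vf.StoppingPolicy(mode="scaled-residual", tolerance=1e-14)
        u, trace = vf.pcg_solve(op, np.array([1.0, 2.0]), policy=policy)
        np.testing.assert_allclose(u, [1 / 11, 7 / 11], atol=1e-12)
        assert trace.iterations <= 2

    def test_exact_initial_guess_stops_immediately(self):
        op = MatrixOperator([[4.0, 1.0], [1.0, 3.0]])
        u0 = np.array([1 / 11, 7 / 11])
        policy = vf.StoppingPolicy(mode="scaled-residual", tolerance=1e-10)
        u, trace = vf.pcg_solve(op, np.array([1.0, 2.0]), u0=u0, policy=policy)
        assert trace.iterations <= 1
        assert trace.converged

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_sparse_solve(self, law, seed):
        load = vf.UniaxialCompression(strain=0.01, end_condition="clamped")
        model = random_grayscale_model((4, 4, 4), seed=seed)
        *_, op, B, monitor = build_system(model, law, load)
        u_ref = spla.spsolve(op.assemble().tocsc(), B)
        policy = vf.StoppingPolicy(mode="scaled-residual", tolerance=1e-12)
        u, _ = vf.pcg_solve(op, B, policy=policy)
        assert np.abs(u - u_ref).max() <= 1e-8 * np.abs(u_ref).max()

    def test_a_norm_error_nonincreasing(self, law):
        load = vf.UniaxialCompression(strain=0.01, end_condition="clamped")
        model = random_grayscale_model((3, 3, 3), seed=0)
        *_, op, B, _ = build_system(model, law, load)
        A = op.assemble().toarray()
        u_star = np.linalg.solve(A, B)

        errors = []

        def monitor(it, u):
            e = u - u_star
            errors.append(float(e @ A @ e))
            return 1.0

        policy = vf.StoppingPolicy(mode="fixed-iterations", max_iterations=60)
        vf.pcg_solve(op, B, policy=policy, monitor=monitor)
        diffs = np.diff(errors)
        assert (diffs <= 1e-10 * max(errors)).all()

    def test_estimated_error_mode_requires_monitor(self, law):
        model = vf.solid_block((2, 2, 2))
        load = vf.UniaxialCompression(strain=0.01)
        *_, op, B, _ = build_system(model, law, load)
        with pytest.raises(ValueError, match="monitor"):
            vf.pcg_solve(op, B, policy=vf.StoppingPolicy())

    def test_max_iterations_flagged_unconverged(self, law, load):
        model = vf.plate_rod_lattice((16, 16, 16))
        *_, op, B, monitor = build_system(model, law, load)
        policy = vf.StoppingPolicy(mode="scaled-residual", tolerance=1e-14, max_iterations=5)
        u, trace = vf.pcg_solve(op, B, policy=policy)
        assert not trace.converged
        assert trace.iterations == 5


class TestScaledResidual:
    def test_basic_values(self):
        B = np.array([3.0, 4.0])
        assert vf.scaled_residual(np.zeros(2), B) == 0.0
        assert vf.scaled_residual(B, B) == 1.0

    def test_zero_rhs_undefined(self):
        with pytest.raises(ValueError):
            vf.scaled_residual(np.ones(2), np.zeros(2))

    def test_recorded_series_reaches_tolerance(self, law, load):
        model = vf.plate_rod_lattice((16, 16, 16))
        *_, op, B, monitor = build_system(model, law, load)
        policy = vf.StoppingPolicy(mode="scaled-residual", tolerance=1e-8)
        _, trace = vf.pcg_solve(op, B, policy=policy)
        assert trace.scaled_residuals[-1] <= 1e-8
        assert trace.scaled_residuals[0] > trace.scaled_residuals[-1]


class TestEstimateRelativeError:
    def test_exact_exponential_series(self):
        """S_n = 1 + e^{-0.1 n}: slope recovered exactly; the finite
        difference biases the estimate by (e^0.1 - 1)/0.1 ~ 1.052."""
        n = np.arange(0, 80)
        S = 1.0 + np.exp(-0.1 * n)
        est, slope, _ = estimate_relative_error(S, window=30)
        assert slope == pytest.approx(-0.1, abs=1e-6)
        true = np.exp(-0.1 * n[-1]) / S[-1]
        assert 0.9 <= est / true <= 1.1

    def test_constant_series_unavailable(self):
        assert estimate_relative_error(np.ones(50), window=30) is None

    def test_growing_series_unavailable(self):
        n = np.arange(0, 50)
        assert estimate_relative_error(1.0 + np.exp(0.05 * n), window=30) is None

    def test_too_short_series_unavailable(self):
        assert estimate_relative_error(np.exp(-0.1 * np.arange(10)), window=30) is None

    def test_factor_two_tracking_on_lattice_solve(self, law, load):
        """In the exponential regime the estimate tracks the true error
        (vs a long reference solve) to within a factor of about two on
        average."""
        model = vf.plate_rod_lattice((24, 24, 24))
        *_, op, B, monitor = build_system(model, law, load)
        ref_policy = vf.StoppingPolicy(mode="scaled-residual", tolerance=1e-13,
                                       max_iterations=20000)
        u_ref, _ = vf.pcg_solve(op, B, policy=ref_policy)
        S_star = monitor(0, u_ref)
        run_policy = vf.StoppingPolicy(mode="fixed-iterations", max_iterations=200)
        _, trace = vf.pcg_solve(op, B, policy=run_policy, monitor=monitor)
        S = np.array(trace.stress)
        true_err = np.abs(S - S_star) / np.abs(S_star)
        log_ratios = []
        for it in range(36, len(S)):
            fit = estimate_relative_error(S[: it + 1], 30)
            if fit is None:
                continue
            est = fit[0]
            # exponential regime: estimator active and well above round-off
            if est <= 0.2 and true_err[it] > 1e-4:
                log_ratios.append(np.log2(est / true_err[it]))
        assert len(log_ratios) > 20
        assert abs(np.mean(log_ratios)) <= 1.0  # geometric mean within 2x

    def test_stopping_at_one_percent_bounds_true_error(self, law, load):
        """Estimated-error stopping at 1% leaves a true stress error
        within the factor-two guarantee (<= 2%)."""
        for seed in (0, 1):
            model = vf.random_porous((24, 24, 24), 0.15, seed=seed)
            model, bcs, dm, op, B, monitor = build_system(model, law, load)
            ref_policy = vf.StoppingPolicy(mode="scaled-residual", tolerance=1e-12,
                                           max_iterations=20000)
            u_ref, _ = vf.pcg_solve(op, B, policy=ref_policy)
            S_star = monitor(0, u_ref)
            u, trace = vf.pcg_solve(op, B, policy=vf.StoppingPolicy(tolerance=0.01),
                                    monitor=monitor)
            assert trace.converged
            assert abs(monitor(0, u) - S_star) / abs(S_star) <= 0.02


class TestPartition:
    def test_single_region_covers_everything(self, law, load):
        model = vf.plate_rod_lattice((16, 16, 16))
        model, bcs, dm, op, B, _ = build_system(model, law, load)
        part = vf.partition_z(dm, model, 1)
        assert part.n_regions == 1
        assert part.regions[0].inner.size == dm.n_free
        assert part.regions[0].outer.size == 0

    def test_solid_block_split_at_middle_layer(self, law, load):
        model = vf.solid_block((8, 8, 8))
        model, bcs, dm, op, B, _ = build_system(model, law, load)
        part = vf.partition_z(dm, model, 2)
        r0, r1 = part.regions
        assert r0.z_hi == r1.z_lo
        # prefix-sum oracle: balanced to within one vertex layer's worth
        free = dm.var_id >= 0
        per_layer = free.sum(axis=(0, 1, 3))
        assert abs(r0.inner.size - r1.inner.size) <= per_layer.max()
        assert r0.z_hi in (4, 5)  # cut at the middle vertex layer

    def test_inner_sets_partition_free_variables(self, law, load):
        model = vf.random_porous((16, 16, 16), 0.2, seed=1)
        model, bcs, dm, op, B, _ = build_system(model, law, load)
        for K in (2, 3, 4):
            part = vf.partition_z(dm, model, K)
            all_inner = np.concatenate([r.inner for r in part.regions])
            assert np.array_equal(np.sort(all_inner), np.arange(dm.n_free))

    def test_outer_vertices_are_neighbor_inner(self, law, load):
        model = vf.solid_block((6, 6, 6))
        model, bcs, dm, op, B, _ = build_system(model, law, load)
        part = vf.partition_z(dm, model, 3)
        for k, reg in enumerate(part.regions):
            neighbors = set()
            if k > 0:
                neighbors.update(part.regions[k - 1].inner.tolist())
            if k < 2:
                neighbors.update(part.regions[k + 1].inner.tolist())
            assert set(reg.outer.tolist()) <= neighbors

    def test_too_many_regions_rejected(self, law, load):
        model = vf.solid_block((4, 4, 4))
        model, bcs, dm, op, B, _ = build_system(model, law, load)
        with pytest.raises(ValueError):
            vf.partition_z(dm, model, 5)

    def test_duplication_overhead_formula_example(self):
        # 8 sub-regions on a 100-layer volume duplicate ~14% of vertices
        assert vf.overhead_fraction(8, 100) == pytest.approx(0.14)


class TestPartitionedPcg:
    def test_single_region_bitwise_identical_to_serial(self, law, load):
        model = vf.plate_rod_lattice((16, 16, 16))
        model, bcs, dm, op, B, monitor = build_system(model, law, load)
        policy = vf.StoppingPolicy(mode="fixed-iterations", max_iterations=40)
        u_serial, tr_s = vf.pcg_solve(op, B, policy=policy, monitor=monitor)
        part = vf.partition_z(dm, model, 1)
        u_part, tr_p = vf.partitioned_pcg(op, B, policy=policy, partition=part,
                                          monitor=monitor)
        np.testing.assert_array_equal(u_serial, u_part)
        assert tr_s.alphas == tr_p.alphas

    @pytest.mark.parametrize("K", [2, 4])
    def test_alpha_agreement_with_serial(self, law, load, K):
        model = vf.plate_rod_lattice((16, 16, 16))
        model, bcs, dm, op, B, monitor = build_system(model, law, load)
        policy = vf.StoppingPolicy(mode="fixed-iterations", max_iterations=50)
        _, tr_s = vf.pcg_solve(op, B, policy=policy, monitor=monitor)
        part = vf.partition_z(dm, model, K)
        _, tr_p = vf.partitioned_pcg(op, B, policy=policy, partition=part,
                                     monitor=monitor)
        a_s, a_p = np.array(tr_s.alphas), np.array(tr_p.alphas)
        assert np.abs(a_s - a_p).max() <= 1e-12 * np.abs(a_s).max()

    @pytest.mark.parametrize("K", [2, 4])
    def test_final_stiffness_independent_of_partitioning(self, law, load, K):
        model = vf.plate_rod_lattice((24, 24, 24))
        model, bcs, dm, op, B, monitor = build_system(model, law, load)
        policy = vf.StoppingPolicy(mode="scaled-residual", tolerance=1e-10)
        u_serial, _ = vf.pcg_solve(op, B, policy=policy, monitor=monitor)
        part = vf.partition_z(dm, model, K)
        u_part, _ = vf.partitioned_pcg(op, B, policy=policy, partition=part,
                                       monitor=monitor)
        s_serial = monitor(0, u_serial)
        s_part = monitor(0, u_part)
        assert abs(s_part - s_serial) <= 1e-8 * abs(s_serial)
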