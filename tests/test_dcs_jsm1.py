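"""JSM-1 joint reconstruction and group-median aggregation."""

import numpy as np
import pytest

from m2hsn import (
    BandSet,
    JSM1Problem,
    Measurement,
    build_jsm1_system,
    dcs_gm,
    default_grid,
    difference_matrix,
    group_pixels,
    reconstruct_dcs_set,
    solve_jsm1,
    synthesis_matrix,
)
from m2hsn.dcs_jsm1 import check_consistency
from m2hsn.errors import DimensionError, InputError
from m2hsn.sensing import SensingOperator, assign_heterogeneous


def measure(band_set, x):
    return Measurement(band_set, SensingOperator(band_set).select(x))


class TestTransforms:
    def test_difference_matrix_annihilates_constants(self):
        D = difference_matrix(6)
        np.testing.assert_array_equal(D @ np.full(6, 3.7), 0.0)
        assert np.linalg.matrix_rank(D) == 5

    def test_synthesis_inverts_differencing(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(7)
        S = synthesis_matrix(7)
        theta = np.concatenate([[x[0]], np.diff(x)])
        np.testing.assert_allclose(S @ theta, x, atol=1e-12)


class TestSystemAssembly:
    def test_stacked_dimensions(self, grid40):
        x = np.zeros(40)
        band_sets = assign_heterogeneous(64, 40, 8, seed=0)
        problem = JSM1Problem(grid40, [measure(b, x) for b in band_sets])
        A, y = build_jsm1_system(problem)
        assert A.shape == (512, 65 * 40)
        assert y.shape == (512,)

    def test_single_node_doubles_unknowns(self, grid40):
        bs = BandSet(np.arange(8), 40)
        problem = JSM1Problem(grid40, [measure(bs, np.linspace(0, 1, 40))])
        A, _ = build_jsm1_system(problem)
        assert A.shape == (8, 2 * 40)

    def test_constant_signal_needs_only_offset_coefficient(self, grid40):
        c = 0.42
        band_sets = assign_heterogeneous(3, 40, 5, seed=1)
        problem = JSM1Problem(grid40, [measure(b, np.full(40, c)) for b in band_sets])
        A, y = build_jsm1_system(problem)
        theta = np.zeros(4 * 40)
        theta[0] = c  # the common offset alone
        np.testing.assert_allclose(A @ theta, y, atol=1e-12)


class TestSolve:
    def test_identical_piecewise_constant_group_recovered_exactly(self, grid40):
        """Nodes sharing one two-plateau spectrum, heterogeneous 4-band sets
        jointly covering the grid: joint recovery is exact."""
        x = np.where(np.arange(40) < 18, 0.2, 0.6)
        band_sets = assign_heterogeneous(64, 40, 4, seed=0)
        values = np.tile(x, (64, 1))
        est = reconstruct_dcs_set(values, band_sets, group_size=64,
                                  grouping_seed=0, grid=grid40)
        assert np.sqrt(np.mean((est - values) ** 2)) < 1e-6

    def test_solution_matches_l0_oracle_on_reduced_instance(self):
        """J=1, N=8, bands straddling the step: the exhaustive oracle confirms
        a 2-sparse exact representation exists, and the joint SL0 solve
        reconstructs the same signal it encodes (the common/innovation split
        of the offset itself is not unique and is not compared)."""
        from m2hsn import l0_oracle

        grid = default_grid(8)
        x = np.where(np.arange(8) < 3, 0.3, 0.8)
        bs = BandSet(np.array([0, 2, 3, 7]), 8)
        problem = JSM1Problem(grid, [measure(bs, x)])
        A, y = build_jsm1_system(problem)
        oracle = l0_oracle(A, y, max_support=2)
        assert oracle is not None and oracle.n_nonzero == 2
        S = synthesis_matrix(8)
        x_oracle = S @ (oracle.coefficients[:8] + oracle.coefficients[8:])
        np.testing.assert_allclose(x_oracle, x, atol=1e-9)
        sol = solve_jsm1(problem)
        np.testing.assert_allclose(sol.reconstructions[0].reflectance, x, atol=1e-8)

    def test_zero_measurements_give_zero_solution(self, grid40):
        band_sets = assign_heterogeneous(4, 40, 5, seed=2)
        problem = JSM1Problem(grid40, [Measurement(b, np.zeros(5)) for b in band_sets])
        sol = solve_jsm1(problem)
        np.testing.assert_allclose(sol.common.reflectance, 0.0, atol=1e-10)
        for z in sol.innovations:
            np.testing.assert_allclose(z.reflectance, 0.0, atol=1e-10)

    def test_single_deviating_node_carries_the_innovation(self, grid40):
        """One node has an extra step (within its measured range); its
        innovation absorbs it while the others' stay at zero."""
        x = np.where(np.arange(40) < 18, 0.2, 0.6)
        x_dev = x.copy()
        x_dev[30:] += 0.15
        band_sets = list(assign_heterogeneous(64, 40, 4, seed=0))
        # ensure the deviating node measures both sides of its extra step
        band_sets[3] = BandSet(np.array([0, 20, 28, 33]), 40)
        values = np.tile(x, (64, 1))
        values[3] = x_dev
        problem = JSM1Problem(grid40, [measure(b, v) for b, v in zip(band_sets, values)])
        sol = solve_jsm1(problem)
        recs = np.stack([r.reflectance for r in sol.reconstructions])
        np.testing.assert_allclose(recs, values, atol=1e-6)
        others = [np.max(np.abs(sol.innovations[j].reflectance))
                  for j in range(64) if j != 3]
        assert max(others) < 1e-6

    def test_measurement_consistency_invariant(self, grid40, mixed_splits):
        values = mixed_splits["eval"].values[:6]
        band_sets = assign_heterogeneous(6, 40, 6, seed=5)
        problem = JSM1Problem(grid40, [measure(b, v) for b, v in zip(band_sets, values)])
        sol = solve_jsm1(problem)
        assert check_consistency(sol, problem) < 1e-6

    def test_homogeneous_band_sets_leave_unmeasured_bands_undetermined(self, grid40):
        """The homogeneous network cannot infer unmeasured bands from JSM-1
        alone, no matter how many nodes share the band set."""
        x = np.where(np.arange(40) < 18, 0.2, 0.6)
        bs = BandSet(np.array([1, 5, 9, 13]), 40)  # misses the step at 18
        unmeasured = np.setdiff1d(np.arange(40), bs.indices)
        errors = []
        for j_nodes in (4, 16, 64):
            values = np.tile(x, (j_nodes, 1))
            est = reconstruct_dcs_set(values, [bs] * j_nodes, group_size=64,
                                      grouping_seed=0, grid=grid40)
            err = np.sqrt(np.mean((est[:, unmeasured] - values[:, unmeasured]) ** 2))
            errors.append(err)
        assert min(errors) > 0.05  # does not converge to zero with J


class TestGrouping:
    def test_exact_partition(self):
        groups = group_pixels(128, 64, seed=0)
        assert [len(g) for g in groups] == [64, 64]

    def test_remainder_group(self):
        groups = group_pixels(100, 64, seed=0)
        assert [len(g) for g in groups] == [64, 36]

    def test_seeded_determinism(self):
        a = group_pixels(50, 8, seed=3)
        b = group_pixels(50, 8, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_empty_set_rejected(self):
        with pytest.raises(InputError):
            group_pixels(0, 8, seed=0)


class TestGroupMedian:
    def test_single_estimate_is_identity(self):
        est = np.random.default_rng(0).uniform(0, 1, (1, 5, 7))
        np.testing.assert_array_equal(dcs_gm(est), est[0])

    def test_median_of_five(self):
        est = np.array([[0.2], [0.21], [0.19], [0.9], [0.2]])
        assert dcs_gm(est)[0] == pytest.approx(0.2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        est = rng.uniform(0, 1, (5, 4, 6))
        perm = rng.permutation(5)
        np.testing.assert_array_equal(dcs_gm(est), dcs_gm(est[perm]))

    def test_median_discards_a_corrupted_grouping(self, grid40):
        """With one corrupted estimate among L=5, the group median beats the
        average single-grouping error."""
        rng = np.random.default_rng(2)
        truth = rng.uniform(0.1, 0.9, (10, 40))
        estimates = np.stack([truth + rng.normal(0, 0.01, truth.shape) for _ in range(5)])
        estimates[3] += 0.5  # one bad grouping
        med = dcs_gm(estimates)
        med_rmse = np.sqrt(np.mean((med - truth) ** 2))
        single_rmses = [np.sqrt(np.mean((estimates[i] - truth) ** 2)) for i in range(5)]
        assert med_rmse <= min(np.median(single_rmses), np.mean(single_rmses))

    def test_ragged_input_rejected(self):
        with pytest.raises(DimensionError):
            dcs_gm(np.zeros((2, 3, 4, 5)))
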