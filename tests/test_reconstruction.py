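import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osemeat.phantom_geometry import ImageGrid, generate_shepp_logan, make_geometry
from osemeat.projector import build_system_matrix, forward_project
from osemeat.reconstruction import (
    PartitionError,
    ReconConfig,
    ReconState,
    apply_update,
    compute_correction,
    compute_residual,
    init_image,
    mlem_reconstruct,
    osem_reconstruct,
    partition_subsets,
    poisson_log_likelihood,
    reconstruction_error,
)


class TestPartition:
    def test_thirty_subsets_of_six(self):
        p = partition_subsets(180, 6)
        assert p.L == 30
        assert all(len(s) == 6 for s in p.subsets)
        # stride interleave: each subset uniformly covers [0, 180) mod 30
        assert p.subsets[0] == [0, 30, 60, 90, 120, 150]

    def test_single_subset_degenerates_to_mlem(self):
        p = partition_subsets(180, 180)
        assert p.L == 1
        assert p.subsets[0] == list(range(180))
        assert p.order == [0]

    def test_farthest_first_order_on_four_subsets(self):
        """Enumerable case: 8 angles in 4 subsets; the greedy order visits
        the subset at 90 degrees of lead separation before the neighbors."""
        p = partition_subsets(8, 2, "optimized")
        assert p.subsets == [[0, 4], [1, 5], [2, 6], [3, 7]]
        assert p.order == [0, 2, 1, 3]

    def test_sequential_order_is_identity(self):
        p = partition_subsets(60, 6, "sequential")
        assert p.order == list(range(10))

    def test_indivisible_partition_rejected(self):
        with pytest.raises(PartitionError):
            partition_subsets(180, 7)

    @given(
        per_subset=st.integers(1, 8),
        L=st.integers(1, 12),
        strategy=st.sampled_from(["sequential", "optimized"]),
    )
    @settings(deadline=None, max_examples=50)
    def test_partition_properties(self, per_subset, L, strategy):
        """Disjoint, covering, balanced — for every valid configuration."""
        n = per_subset * L
        p = partition_subsets(n, per_subset, strategy)
        flat = [i for s in p.subsets for i in s]
        assert sorted(flat) == list(range(n))
        assert all(len(s) == per_subset for s in p.subsets)
        assert sorted(p.order) == list(range(L))
        # uniform angular coverage: within-subset stride is exactly L
        for s in p.subsets:
            assert all(b - a == L for a, b in zip(s, s[1:]))


class TestUpdateSteps:
    def test_init_image_is_all_ones(self):
        grid = ImageGrid(np.zeros((2, 2)))
        img = init_image(grid)
        np.testing.assert_array_equal(img.values, np.ones((2, 2)))
        assert img.values.min() > 0

    def test_residual_identity_and_scaling(self):
        theo = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(compute_residual(theo, theo), [1, 1, 1])
        np.testing.assert_array_equal(compute_residual(2 * theo, theo), [2, 2, 2])

    def test_residual_zero_over_zero_is_zero(self):
        r = compute_residual(np.zeros(3), np.zeros(3), epsilon=1e-12)
        np.testing.assert_array_equal(r, np.zeros(3))

    def test_negative_observation_rejected(self):
        with pytest.raises(ValueError):
            compute_residual(np.array([-1.0]), np.array([1.0]))

    def test_unit_residual_gives_unit_correction(self, small_system):
        geom, grid, A = small_system
        rows = A.rays_for_angles([0, 2])
        c = compute_correction(A, np.ones(rows.size), [0, 2])
        np.testing.assert_allclose(c, 1.0, atol=1e-12)

    def test_constant_residual_gives_constant_correction(self, small_system):
        geom, grid, A = small_system
        rows = A.rays_for_angles([1, 3])
        sens = np.asarray(A.weights[rows].sum(axis=0)).ravel()
        c = compute_correction(A, np.full(rows.size, 2.0), [1, 3])
        np.testing.assert_allclose(c[sens > 0], 2.0, atol=1e-12)
        np.testing.assert_allclose(c[sens == 0], 1.0)

    def test_correction_matches_dense_double_loop(self, small_system):
        """The sparse backprojection ratio equals an explicit per-pixel
        double loop over the subset's rays."""
        geom, grid, A = small_system
        subset = [0, 3]
        rows = A.rays_for_angles(subset)
        rng = np.random.default_rng(11)
        residual = rng.uniform(0.5, 2.0, rows.size)
        dense = A.weights.toarray()
        expected = np.ones(A.n_pixels)
        for j in range(A.n_pixels):
            num = sum(dense[i, j] * residual[k] for k, i in enumerate(rows))
            den = sum(dense[i, j] for i in rows)
            if den > 0:
                expected[j] = num / den
        got = compute_correction(A, residual, subset)
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_empty_subset_rejected(self, small_system):
        geom, grid, A = small_system
        with pytest.raises(PartitionError):
            compute_correction(A, np.empty(0), [])

    def test_apply_update_arithmetic(self):
        state = ReconState(image=ImageGrid(np.array([[1.0, 2.0]])))
        apply_update(state, np.array([[3.0, 0.5]]))
        np.testing.assert_array_equal(state.image.values, [[3.0, 1.0]])
        apply_update(state, np.ones((1, 2)))
        np.testing.assert_array_equal(state.image.values, [[3.0, 1.0]])

    def test_zero_pixel_is_absorbing(self):
        state = ReconState(image=ImageGrid(np.array([[0.0, 1.0]])))
        apply_update(state, np.array([[5.0, 5.0]]))
        assert state.image.values[0, 0] == 0.0

    def test_negative_correction_rejected(self):
        state = ReconState(image=ImageGrid(np.ones((1, 2))))
        with pytest.raises(ValueError):
            apply_update(state, np.array([[-0.1, 1.0]]))


class TestErrorMetric:
    def test_exact_recovery_is_zero(self):
        t = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert reconstruction_error(t, t) == 0.0

    def test_doubling_gives_unit_error(self):
        t = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert reconstruction_error(2 * t, t) == pytest.approx(1.0)

    def test_constant_offset_hand_case(self):
        truth = np.array([[3.0, 0.0], [0.0, 4.0]])  # norm 5
        recon = truth + 1.0  # difference norm 2
        assert reconstruction_error(recon, truth) == pytest.approx(2.0 / 5.0)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_error(np.ones((2, 2)), np.zeros((2, 2)))


class TestLogLikelihood:
    def test_maximized_at_unit_scale_for_consistent_data(self, small_system):
        geom, grid, A = small_system
        rng = np.random.default_rng(3)
        g = rng.uniform(0.1, 1.0, (8, 8))
        y = forward_project(A, g)
        ll_at = lambda t: poisson_log_likelihood(y, A, t * g)
        base = ll_at(1.0)
        for t in (0.5, 0.9, 1.1, 2.0):
            assert ll_at(t) < base

    def test_guard_inactive_when_projection_positive(self, small_system):
        geom, grid, A = small_system
        g = np.ones((8, 8))
        y = forward_project(A, g)
        a = poisson_log_likelihood(y, A, g, epsilon=1e-12)
        b = poisson_log_likelihood(y, A, g, epsilon=2e-12)
        assert a == b


class TestIterativeReconstruction:
    def test_osem_single_subset_equals_mlem_bitwise(self, scaled_recon_setup):
        truth, geom, A, y = scaled_recon_setup
        cfg = ReconConfig(n_iterations=3, per_subset=geom.n_angles)
        part = partition_subsets(geom.n_angles, geom.n_angles)
        s_osem = osem_reconstruct(y, A, part, cfg)
        s_mlem = mlem_reconstruct(y, A, cfg)
        assert np.array_equal(s_osem.image.values, s_mlem.image.values)

    def test_truth_is_a_fixed_point_of_consistent_data(self, scaled_recon_setup):
        truth, geom, A, y = scaled_recon_setup
        part = partition_subsets(geom.n_angles, 6)
        cfg = ReconConfig(n_iterations=10, per_subset=6)
        state = osem_reconstruct(y, A, part, cfg, initial=truth)
        assert np.max(np.abs(state.image.values - truth.values)) < 1e-10

    def test_mlem_log_likelihood_monotone_on_noisy_data(self, scaled_recon_setup):
        """EM ascent holds for inconsistent (noisy) data too."""
        truth, geom, A, y = scaled_recon_setup
        rng = np.random.default_rng(7)
        noisy = rng.poisson(y.values * 2.0).astype(float)
        state = mlem_reconstruct(noisy, A, ReconConfig(n_iterations=15))
        ll = np.array(state.loglik_history)
        assert np.all(np.diff(ll) >= -1e-9 * np.abs(ll[:-1]))

    def test_reconstruction_stays_nonnegative(self, scaled_recon_setup):
        truth, geom, A, y = scaled_recon_setup
        part = partition_subsets(geom.n_angles, 6)
        state = osem_reconstruct(y, A, part, ReconConfig(n_iterations=5))
        assert state.image.values.min() >= 0.0

    def test_matches_dense_loop_oracle(self):
        """Sparse OSEM equals an independently coded dense implementation
        on a 32x32 instance, 36 views in 6 subsets, 5 iterations."""
        truth = generate_shepp_logan(32)
        geom = make_geometry(5.0, 180.0, 47)
        A = build_system_matrix(geom, truth)
        y = forward_project(A, truth)
        part = partition_subsets(36, 6, "optimized")
        state = osem_reconstruct(y, A, part, ReconConfig(n_iterations=5))

        dense = A.weights.toarray()
        nd = geom.n_detectors
        g = np.ones(A.n_pixels)
        for _ in range(5):
            for m in part.order:
                rows = np.concatenate(
                    [np.arange(a * nd, (a + 1) * nd) for a in part.subsets[m]]
                )
                sub = dense[rows]
                yhat = sub @ g
                r = y.values[rows] / np.maximum(yhat, 1e-12)
                num = sub.T @ r
                den = sub.sum(axis=0)
                c = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
                g = g * c
        np.testing.assert_allclose(
            state.image.values.ravel(), g, rtol=1e-9, atol=1e-12
        )

    def test_error_decreases_with_iterations(self, scaled_recon_setup):
        truth, geom, A, y = scaled_recon_setup
        part = partition_subsets(geom.n_angles, 6)
        state = osem_reconstruct(y, A, part, ReconConfig(n_iterations=20), truth=truth)
        assert len(state.error_history) == state.k == 20
        assert state.error_history[19] < state.error_history[0]

    def test_osem_one_iteration_beats_mlem_one_iteration(self, scaled_recon_setup):
        truth, geom, A, y = scaled_recon_setup
        part = partition_subsets(geom.n_angles, 6, "optimized")
        e_osem = osem_reconstruct(
            y, A, part, ReconConfig(n_iterations=1), truth=truth
        ).error_history[0]
        e_mlem = mlem_reconstruct(
            y, A, ReconConfig(n_iterations=1), truth=truth
        ).error_history[0]
        assert e_osem <= e_mlem

    def test_optimized_ordering_beats_sequential(self, scaled_recon_setup):
        truth, geom, A, y = scaled_recon_setup
        cfg = ReconConfig(n_iterations=1)
        e_opt = osem_reconstruct(
            y, A, partition_subsets(geom.n_angles, 6, "optimized"), cfg, truth=truth
        ).error_history[0]
        e_seq = osem_reconstruct(
            y, A, partition_subsets(geom.n_angles, 6, "sequential"), cfg, truth=truth
        ).error_history[0]
        assert e_opt <= e_seq

    def test_negative_sinogram_rejected(self, small_system):
        geom, grid, A = small_system
        part = partition_subsets(geom.n_angles, 1)
        with pytest.raises(ValueError):
            osem_reconstruct(-np.ones(A.n_rays), A, part)
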