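import itertools

import numpy as np
import pytest

from mwfpipe.epg import DecayCurve, epg_echo_amplitudes_batch
from mwfpipe.spectrum import (
    BasisCache,
    FitConfig,
    T2Distribution,
    build_decay_basis,
    compute_mwf,
    estimate_flip_angle,
    fit_volume,
    fit_voxel,
    make_t2_grid,
    nnls_solve,
    regularized_nnls,
)

CANDIDATES = np.linspace(50.0, 180.0, 8)


def brute_force_nnls(A, b):
    """Independent oracle: enumerate every active set, solve the
    equality-constrained least squares, keep the feasible minimizer."""
    n = A.shape[1]
    best_x, best_obj = None, np.inf
    for active in itertools.product([0, 1], repeat=n):
        free = [j for j in range(n) if active[j]]
        x = np.zeros(n)
        if free:
            sol, *_ = np.linalg.lstsq(A[:, free], b, rcond=None)
            x[free] = sol
        if np.any(x < -1e-9):
            continue
        x = np.clip(x, 0.0, None)
        obj = np.sum((A @ x - b) ** 2)
        if obj < best_obj - 1e-12:
            best_obj, best_x = obj, x
    return best_x, best_obj


class TestT2Grid:
    def test_endpoints(self, grid):
        assert grid.values[0] == pytest.approx(0.015, abs=0)
        assert grid.values[-1] == pytest.approx(2.0, abs=0)
        assert grid.n_points == 40

    def test_second_point_closed_form(self, grid):
        assert grid.values[1] == pytest.approx(0.015 * (2.0 / 0.015) ** (1 / 39), rel=1e-12)
        assert grid.values[1] == pytest.approx(0.017005, abs=5e-7)

    def test_three_point_geometric_mean(self):
        a, r = 0.02, 1.7
        g = make_t2_grid(a, a * r * r, 3)
        assert g.values[1] == pytest.approx(a * r, rel=1e-12)

    @pytest.mark.parametrize("args", [(0.0, 1.0, 5), (1.0, 0.5, 5), (0.1, 1.0, 1)])
    def test_invalid(self, args):
        with pytest.raises(ValueError):
            make_t2_grid(*args)

    def test_constant_ratio(self, grid):
        ratios = grid.values[1:] / grid.values[:-1]
        assert np.max(np.abs(ratios / ratios[0] - 1)) < 1e-12


class TestNnls:
    def test_identity_clipping(self):
        x = nnls_solve(np.eye(2), np.array([3.0, -1.0]))
        assert np.allclose(x, [3.0, 0.0])

    def test_exact_feasible_recovery(self):
        rng = np.random.default_rng(0)
        A = rng.random((8, 4))
        x_true = rng.random(4)
        x = nnls_solve(A, A @ x_true)
        assert np.max(np.abs(x - x_true)) < 1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_active_set_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.random((6, 3))
        b = rng.standard_normal(6)
        x = nnls_solve(A, b)
        x_ref, obj_ref = brute_force_nnls(A, b)
        assert np.sum((A @ x - b) ** 2) == pytest.approx(obj_ref, abs=1e-10)
        assert np.allclose(x, x_ref, atol=1e-8)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            nnls_solve(np.eye(3), np.ones(2))


class TestDecayBasis:
    def test_columns_are_epg_curves(self, grid, train):
        basis = build_decay_basis(grid, 150.0, train)
        direct = epg_echo_amplitudes_batch(grid.values, 1.0, 150.0, train).T
        assert np.array_equal(basis.matrix, direct)
        assert basis.matrix.shape == (32, 40)
        assert basis.matrix.min() >= 0 and basis.matrix.max() <= 1 + 1e-12


class TestEstimateFlipAngle:
    def test_noiseless_180_exact_boundary(self, grid, train, fit_cfg, basis_cache):
        # pools on grid points -> zero residual at the true candidate angle
        b = 0.2 * basis_cache.get(180.0).matrix[:, 2] + 0.8 * basis_cache.get(180.0).matrix[:, 13]
        est = estimate_flip_angle(DecayCurve(b), grid, train, fit_cfg, basis_cache)
        assert est == 180.0

    def test_noiseless_candidate_angle(self, grid, train, fit_cfg, basis_cache, two_pool_curve):
        target = CANDIDATES[6]  # 161.43
        est = estimate_flip_angle(
            DecayCurve(two_pool_curve(target)), grid, train, fit_cfg, basis_cache
        )
        assert est == pytest.approx(target, abs=0.5)

    def test_noiseless_between_candidates(self, grid, train, fit_cfg, basis_cache, two_pool_curve):
        est = estimate_flip_angle(
            DecayCurve(two_pool_curve(130.0)), grid, train, fit_cfg, basis_cache
        )
        assert est == pytest.approx(130.0, abs=2.0)

    def test_all_zero_curve_undefined(self, grid, train, fit_cfg, basis_cache):
        est = estimate_flip_angle(DecayCurve(np.zeros(32)), grid, train, fit_cfg, basis_cache)
        assert np.isnan(est)


class TestRegularizedNnls:
    def test_noiseless_grid_pools_take_mu0_branch(self, grid, train, fit_cfg, basis_cache):
        basis = basis_cache.get(180.0)
        b = 0.3 * basis.matrix[:, 2] + 0.7 * basis.matrix[:, 13]
        dist, chi2_min, chi2_reg, mu = regularized_nnls(DecayCurve(b), basis, fit_cfg)
        assert mu == 0.0
        assert chi2_reg == chi2_min
        # distribution reproduces the pool locations
        assert dist.amplitudes[2] == pytest.approx(0.3, abs=1e-8)
        assert dist.amplitudes[13] == pytest.approx(0.7, abs=1e-8)

    def test_mu0_branch_equals_plain_nnls(self, grid, train, fit_cfg, basis_cache):
        basis = basis_cache.get(180.0)
        b = 0.3 * basis.matrix[:, 2] + 0.7 * basis.matrix[:, 13]
        dist, *_ = regularized_nnls(DecayCurve(b), basis, fit_cfg)
        assert np.allclose(dist.amplitudes, nnls_solve(basis.matrix, b), atol=1e-12)

    def test_noisy_ratio_in_window(self, grid, train, fit_cfg, basis_cache, two_pool_curve):
        rng = np.random.default_rng(42)
        clean = two_pool_curve(160.0)
        noisy = np.abs(clean + rng.normal(0, clean[0] / 100, clean.size))
        basis = basis_cache.get(
            estimate_flip_angle(DecayCurve(noisy), grid, train, fit_cfg, basis_cache)
        )
        _, chi2_min, chi2_reg, mu = regularized_nnls(DecayCurve(noisy), basis, fit_cfg)
        assert fit_cfg.reg_ratio_lo <= chi2_reg / chi2_min <= fit_cfg.reg_ratio_hi
        assert mu > 0

    def test_misfit_monotone_in_mu(self, grid, train, basis_cache, two_pool_curve):
        rng = np.random.default_rng(3)
        clean = two_pool_curve(150.0)
        b = np.abs(clean + rng.normal(0, clean[0] / 100, clean.size))
        A = basis_cache.get(150.0).matrix
        eye = np.eye(A.shape[1])
        b_aug = np.concatenate([b, np.zeros(A.shape[1])])
        chis = []
        for mu in [0.0, 1e-6, 1e-4, 1e-2, 1.0, 100.0]:
            x = nnls_solve(np.vstack([A, np.sqrt(mu) * eye]), b_aug)
            chis.append(np.sum((A @ x - b) ** 2))
        assert np.all(np.diff(chis) >= -1e-12)


class TestComputeMwf:
    def test_single_spike_inside_window(self, grid):
        amps = np.zeros(40)
        k20 = int(np.argmin(np.abs(grid.values - 0.020)))
        amps[k20] = 5.0
        assert compute_mwf(T2Distribution(amps), grid) == 1.0

    def test_two_spike_ratio(self, grid):
        amps = np.zeros(40)
        amps[int(np.argmin(np.abs(grid.values - 0.020)))] = 0.3
        amps[int(np.argmin(np.abs(grid.values - 0.080)))] = 0.7
        assert compute_mwf(T2Distribution(amps), grid) == pytest.approx(0.3, rel=1e-12)

    def test_zero_distribution_undefined(self, grid):
        assert np.isnan(compute_mwf(T2Distribution(np.zeros(40)), grid))

    def test_lower_edge_grid_point_included(self, grid):
        amps = np.zeros(40)
        amps[0] = 1.0  # exactly 0.015 s, the window's lower edge
        assert compute_mwf(T2Distribution(amps), grid, (0.015, 0.040)) == 1.0

    def test_window_outside_grid_errors(self, grid):
        with pytest.raises(ValueError):
            compute_mwf(T2Distribution(np.ones(40)), grid, (3.0, 4.0))

    def test_windowed_plus_complement_is_one(self, grid):
        rng = np.random.default_rng(1)
        amps = rng.random(40)
        dist = T2Distribution(amps)
        inside = compute_mwf(dist, grid, (0.015, 0.040))
        outside = 1.0 - inside
        sel = grid.values <= 0.040 * (1 + 1e-9)
        assert inside == pytest.approx(amps[sel].sum() / amps.sum(), rel=1e-12)
        assert inside + outside == 1.0


class TestFitVoxel:
    def test_noiseless_two_pool_180(self, grid, train, fit_cfg, basis_cache, two_pool_curve):
        curve = DecayCurve(two_pool_curve(180.0, mwf=0.2, t2_ie=grid.values[13]))
        res = fit_voxel(curve, grid, train, fit_cfg, basis_cache)
        assert res.mwf == pytest.approx(0.200, abs=0.005)

    def test_noiseless_two_pool_140(self, grid, train, fit_cfg, basis_cache, two_pool_curve):
        curve = DecayCurve(two_pool_curve(140.0, mwf=0.2, t2_ie=grid.values[13]))
        res = fit_voxel(curve, grid, train, fit_cfg, basis_cache)
        assert res.mwf == pytest.approx(0.200, abs=0.01)
        assert res.estimated_angle == pytest.approx(140.0, abs=2.0)

    def test_pure_csf_zero_mwf(self, grid, train, fit_cfg, basis_cache):
        curve = DecayCurve(epg_echo_amplitudes_batch(2.0, 4.0, 180.0, train))
        res = fit_voxel(curve, grid, train, fit_cfg, basis_cache)
        assert res.mwf == pytest.approx(0.0, abs=1e-6)

    def test_scale_invariance(self, grid, train, fit_cfg, basis_cache, two_pool_curve):
        rng = np.random.default_rng(5)
        clean = two_pool_curve(155.0)
        noisy = np.abs(clean + rng.normal(0, clean[0] / 150, clean.size))
        r1 = fit_voxel(DecayCurve(noisy), grid, train, fit_cfg, basis_cache)
        r2 = fit_voxel(DecayCurve(17.3 * noisy), grid, train, fit_cfg, basis_cache)
        assert r2.estimated_angle == pytest.approx(r1.estimated_angle, abs=1e-6)
        assert r2.mwf == pytest.approx(r1.mwf, abs=1e-6)
        assert np.allclose(r2.distribution.amplitudes, 17.3 * r1.distribution.amplitudes,
                           rtol=1e-4, atol=1e-8)

    def test_chi2_invariant(self, grid, train, fit_cfg, basis_cache, two_pool_curve):
        rng = np.random.default_rng(6)
        clean = two_pool_curve(170.0)
        noisy = np.abs(clean + rng.normal(0, clean[0] / 200, clean.size))
        res = fit_voxel(DecayCurve(noisy), grid, train, fit_cfg, basis_cache)
        assert 0.0 <= res.chi2_min <= res.chi2_reg
        assert 0.0 <= res.mwf <= 1.0

    def test_undefined_propagates(self, grid, train, fit_cfg, basis_cache):
        res = fit_voxel(DecayCurve(np.zeros(32)), grid, train, fit_cfg, basis_cache)
        assert not res.defined
        assert np.isnan(res.mwf)


class TestFitVolume:
    def test_single_voxel_equals_fit_voxel(self, grid, train, fit_cfg, basis_cache, two_pool_curve):
        curve = two_pool_curve(165.0)
        vol = curve.reshape(1, 1, 1, -1)
        mask = np.ones((1, 1, 1), dtype=bool)
        mwf_map, angle_map, chi2_map = fit_volume(vol, mask, grid, train, fit_cfg)
        ref = fit_voxel(DecayCurve(curve), grid, train, fit_cfg, basis_cache)
        assert mwf_map[0, 0, 0] == pytest.approx(ref.mwf, abs=1e-12)
        assert angle_map[0, 0, 0] == pytest.approx(ref.estimated_angle, abs=1e-12)
        assert chi2_map[0, 0, 0] == pytest.approx(ref.chi2_reg, rel=1e-9)

    def test_out_of_mask_nan(self, grid, train, fit_cfg, two_pool_curve):
        vol = np.tile(two_pool_curve(160.0), (2, 2, 1, 1))
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, 0, 0] = True
        mwf_map, _, _ = fit_volume(vol, mask, grid, train, fit_cfg)
        assert np.isfinite(mwf_map[0, 0, 0])
        assert np.isnan(mwf_map[1, 1, 0])

    def test_voxel_independence_under_permutation(self, grid, train, fit_cfg, two_pool_curve):
        rng = np.random.default_rng(2)
        vol = np.empty((3, 2, 1, 32))
        for idx in np.ndindex(3, 2, 1):
            clean = two_pool_curve(rng.uniform(130, 180))
            vol[idx] = np.abs(clean + rng.normal(0, clean[0] / 300, 32))
        mask = np.ones((3, 2, 1), dtype=bool)
        a, _, _ = fit_volume(vol, mask, grid, train, fit_cfg)
        flipped, _, _ = fit_volume(vol[::-1], mask[::-1], grid, train, fit_cfg)
        assert np.allclose(a, flipped[::-1], equal_nan=True)

    def test_shape_mismatch_errors(self, grid, train, fit_cfg):
        with pytest.raises(ValueError):
            fit_volume(np.zeros((2, 2, 1, 16)), np.ones((2, 2, 1)), grid, train, fit_cfg)
        with pytest.raises(ValueError):
            fit_volume(np.zeros((2, 2, 1, 32)), np.ones((3, 3, 1)), grid, train, fit_cfg)
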