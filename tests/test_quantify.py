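"""Partial-volume regression: re-gridding, smoothing, solver, recovery."""

import numpy as np
import pytest
from scipy.ndimage import convolve as ndi_convolve

from natsc.calibration import SodiumImage
from natsc.phantom import (
    PhantomTruth,
    TissueFractionMaps,
    build_psf_kernel,
    default_affine,
    lores_affine,
)
from natsc.pipeline import ImagingSimulator
from natsc.quantify import (
    normalized_ventricular_volume,
    regrid_fractions,
    smooth_fractions,
    solve_global_atsc,
)


def _maps(f_gm, f_wm, f_csf, voxel=(2.0, 2.0, 2.0)):
    affine = default_affine(f_gm.shape, voxel)
    return TissueFractionMaps(f_gm, f_wm, f_csf, affine)


class TestRegrid:
    def test_identity_grid(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0, 0.33, (3, 6, 6, 6))
        maps = _maps(*f)
        out = regrid_fractions(maps, maps.affine, maps.grid_shape)
        assert np.allclose(out.f_gm, maps.f_gm)

    def test_uniform_field_any_resolution(self):
        maps = _maps(np.full((6, 6, 6), 0.4), np.zeros((6, 6, 6)), np.zeros((6, 6, 6)))
        target = lores_affine(maps.affine, (2, 2, 2))
        out = regrid_fractions(maps, target, (3, 3, 3))
        assert np.allclose(out.f_gm, 0.4)

    def test_hand_block_mean(self):
        f = np.array([1, 0, 0, 0, 1, 1, 0, 1], dtype=float).reshape(2, 2, 2)
        maps = _maps(f, np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))
        target = lores_affine(maps.affine, (2, 2, 2))
        out = regrid_fractions(maps, target, (1, 1, 1))
        assert out.f_gm[0, 0, 0] == pytest.approx(0.5)

    def test_volume_conservation_on_nested_grids(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0, 0.3, (3, 12, 12, 12))
        maps = _maps(*f)
        target = lores_affine(maps.affine, (3, 3, 3))
        out = regrid_fractions(maps, target, (4, 4, 4))
        # fraction * voxel volume summed is conserved: 27x larger voxels
        assert out.f_gm.sum() * 27 == pytest.approx(maps.f_gm.sum(), rel=1e-9)

    def test_disjoint_fov_rejected(self):
        maps = _maps(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), np.zeros((4, 4, 4)))
        far = maps.affine.copy()
        far[:3, 3] += 1000.0
        with pytest.raises(ValueError, match="disjoint"):
            regrid_fractions(maps, far, (4, 4, 4))

    def test_trilinear_path_for_non_nested_grid(self):
        maps = _maps(np.full((8, 8, 8), 0.4), np.zeros((8, 8, 8)), np.zeros((8, 8, 8)))
        target = default_affine((5, 5, 5), (3.0, 3.0, 3.0))
        out = regrid_fractions(maps, target, (5, 5, 5))
        assert np.allclose(out.f_gm, 0.4, atol=1e-6)


class TestSmooth:
    def _delta(self):
        k = np.zeros((3, 3, 3))
        k[1, 1, 1] = 1.0
        return k

    def test_delta_kernel_identity(self):
        rng = np.random.default_rng(2)
        maps = _maps(*rng.uniform(0, 0.33, (3, 6, 6, 6)))
        out = smooth_fractions(maps, self._delta())
        assert np.allclose(out.f_gm, maps.f_gm)

    def test_constant_field_unchanged(self):
        maps = _maps(np.full((8, 8, 8), 0.3), np.zeros((8, 8, 8)), np.full((8, 8, 8), 0.2))
        ker = build_psf_kernel(56.0, 36.3, (6.0, 6.0, 6.0), kernel_shape=(5, 5, 5))
        out = smooth_fractions(maps, ker)
        assert np.allclose(out.f_gm, 0.3, atol=1e-9)
        assert np.allclose(out.f_csf, 0.2, atol=1e-9)

    def test_step_edge_midpoint(self):
        f = np.zeros((12, 6, 6))
        f[6:] = 1.0
        maps = _maps(f, np.zeros_like(f), np.zeros_like(f))
        ker = np.zeros((5, 1, 1))
        ker[:, 0, 0] = [0.1, 0.2, 0.4, 0.2, 0.1]
        out = smooth_fractions(maps, ker)
        # symmetric kernel: the two voxels flanking the edge average to 1/2
        assert (out.f_gm[5, 0, 0] + out.f_gm[6, 0, 0]) / 2 == pytest.approx(0.5)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(3)
        maps = _maps(*rng.uniform(0, 0.33, (3, 7, 7, 7)))
        ker = build_psf_kernel(56.0, 20.0, (6.0, 6.0, 6.0), kernel_shape=(5, 5, 5))
        out = smooth_fractions(maps, ker)
        oracle = ndi_convolve(maps.f_wm, ker, mode="nearest")
        assert np.allclose(out.f_wm, oracle, atol=1e-9)

    def test_unnormalized_kernel_rejected(self):
        maps = _maps(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="normalized"):
            smooth_fractions(maps, np.ones((3, 3, 3)))


class TestSolver:
    def _image(self, data, affine):
        return SodiumImage(np.asarray(data, dtype=float), affine, {})

    def test_three_voxel_exact_solve(self):
        f_gm = np.array([[[1.0, 0.0, 0.5]]]).reshape(3, 1, 1)
        f_wm = np.array([[[0.0, 1.0, 0.5]]]).reshape(3, 1, 1)
        f_csf = np.zeros((3, 1, 1))
        maps = _maps(f_gm, f_wm, f_csf)
        obs = np.array([35.0, 30.0, 32.5]).reshape(3, 1, 1)
        est = solve_global_atsc(self._image(obs, maps.affine), maps)
        assert est.atsc_gm == pytest.approx(35.0, abs=1e-10)
        assert est.atsc_wm == pytest.approx(30.0, abs=1e-10)
        assert est.residual_rms == pytest.approx(0.0, abs=1e-10)

    def test_single_tissue_design_rejected_as_rank_deficient(self):
        f_gm = np.full((4, 4, 4), 0.8)
        maps = _maps(f_gm, np.zeros((4, 4, 4)), np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="rank-deficient"):
            solve_global_atsc(self._image(f_gm * 35, maps.affine), maps)

    def test_empty_mask_rejected(self):
        zeros = np.zeros((4, 4, 4))
        maps = _maps(zeros, zeros, zeros)
        with pytest.raises(ValueError, match="no voxels"):
            solve_global_atsc(self._image(zeros, maps.affine), maps)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        n = 1000
        f_gm = rng.uniform(0, 0.6, n)
        f_wm = rng.uniform(0, 1 - f_gm)
        f_csf = rng.uniform(0, 1 - f_gm - f_wm)
        obs = 35 * f_gm + 30 * f_wm + 140 * f_csf + rng.normal(0, 1.0, n)
        shape = (10, 10, 10)
        maps = _maps(f_gm.reshape(shape), f_wm.reshape(shape), f_csf.reshape(shape))
        est = solve_global_atsc(self._image(obs.reshape(shape), maps.affine), maps,
                                mask_threshold=0.0)
        A = np.stack([f_gm, f_wm], axis=1)
        y = obs - 140 * f_csf
        oracle = np.linalg.solve(A.T @ A, A.T @ y)
        assert est.atsc_gm == pytest.approx(oracle[0], rel=1e-8)
        assert est.atsc_wm == pytest.approx(oracle[1], rel=1e-8)

    def test_csf_free_variant_recovers_csf(self):
        rng = np.random.default_rng(5)
        n = 512
        f_gm = rng.uniform(0, 0.5, n)
        f_wm = rng.uniform(0, 1 - f_gm)
        f_csf = rng.uniform(0, 1 - f_gm - f_wm)
        obs = 35 * f_gm + 30 * f_wm + 140 * f_csf
        shape = (8, 8, 8)
        maps = _maps(f_gm.reshape(shape), f_wm.reshape(shape), f_csf.reshape(shape))
        est = solve_global_atsc(self._image(obs.reshape(shape), maps.affine), maps,
                                mask_threshold=0.0, csf_free=True)
        assert est.atsc_csf == pytest.approx(140.0, abs=1e-8)


class TestEndToEndRecovery:
    def test_noiseless_recovery_close_to_truth(self, fine_sim):
        gm, wm = fine_sim.quantify(fine_sim.acquire(35.0, 30.0, seed=0))
        assert gm == pytest.approx(35.0, abs=0.35)
        assert wm == pytest.approx(30.0, abs=0.35)

    def test_monotone_in_true_gm(self, geometry, coarse_truth):
        sim = ImagingSimulator(geometry, coarse_truth, noise_level=0.0)
        estimates = [sim.quantify(sim.acquire(c, 30.0, seed=0))[0] for c in (33.0, 35.0, 37.0)]
        assert estimates[0] < estimates[1] < estimates[2]

    def test_csf_spillover_robustness(self, geometry, coarse_truth):
        """Doubling ventricle volume moves tissue aTSC by < 2%."""
        sim1 = ImagingSimulator(geometry, coarse_truth, noise_level=0.0)
        sim2 = ImagingSimulator(
            geometry.scaled_ventricles(2.0), coarse_truth, noise_level=0.0
        )
        gm1, wm1 = sim1.quantify(sim1.acquire(35.0, 30.0, seed=0))
        gm2, wm2 = sim2.quantify(sim2.acquire(35.0, 30.0, seed=0))
        assert abs(gm2 - gm1) / gm1 < 0.02
        assert abs(wm2 - wm1) / wm1 < 0.02

    def test_bias_shrinks_with_noise(self, geometry, coarse_truth):
        errs = []
        for level in (0.05, 0.02, 0.0):
            sim = ImagingSimulator(geometry, coarse_truth, noise_level=level)
            ests = [sim.quantify(sim.acquire(35.0, 30.0, seed=s)) for s in range(3)]
            errs.append(abs(np.mean([e[0] for e in ests]) - 35.0))
        assert errs[0] > errs[1] > errs[2]


class TestVentricularVolume:
    def test_hand_ratio(self):
        assert normalized_ventricular_volume(5000, 5000, 1_000_000) == pytest.approx(0.01)

    def test_zero_ventricles(self):
        assert normalized_ventricular_volume(0, 0, 1_000_000) == 0.0

    def test_unit_rescaling_invariance(self):
        a = normalized_ventricular_volume(4000, 6000, 1.4e6)
        b = normalized_ventricular_volume(4.0, 6.0, 1.4e3)
        assert a == pytest.approx(b)

    def test_bad_etiv_rejected(self):
        with pytest.raises(ValueError):
            normalized_ventricular_volume(1, 1, 0)
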