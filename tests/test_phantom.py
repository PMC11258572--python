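"""Phantom generation, PSF construction and the acquisition forward model."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from natsc.phantom import (
    Ellipsoid,
    PhantomGeometry,
    PhantomTruth,
    background_corner_mask,
    block_average,
    build_psf_kernel,
    eye_occupancy,
    generate_phantom,
    kernel_fwhm_mm,
    parenchymal_noise_sigma,
    simulate_acquisition,
    simulate_study,
)


class TestFractionMaps:
    def test_invariants_on_generated_phantom(self, coarse_phantom):
        fractions, conc = coarse_phantom
        fractions.validate()
        total = fractions.total
        assert total.max() <= 1 + 1e-9
        assert conc.min() >= 0

    def test_pure_tissue_voxel_concentration(self, geometry, coarse_truth):
        fractions, conc = generate_phantom(geometry, coarse_truth)
        pure_gm = fractions.f_gm > 1 - 1e-12
        assert pure_gm.any()
        assert np.allclose(conc[pure_gm], coarse_truth.c_gm)

    def test_background_is_zero(self, geometry, coarse_truth):
        fractions, conc = generate_phantom(geometry, coarse_truth)
        eyes = eye_occupancy(geometry, coarse_truth).sum(axis=0)
        outside = (fractions.total == 0) & (eyes == 0)
        assert outside.any()
        assert np.all(conc[outside] == 0)

    def test_weighted_sum_hand_example(self):
        # 0.5*35 + 0.3*30 + 0.2*140 = 17.5 + 9 + 28 = 54.5 mM
        assert 0.5 * 35 + 0.3 * 30 + 0.2 * 140 == pytest.approx(54.5)
        # and the generator composes concentrations exactly this way
        truth = PhantomTruth(hi_res_voxel_mm=(3.0,) * 3)
        geometry = PhantomGeometry()
        fractions, conc = generate_phantom(geometry, truth)
        mixed = (fractions.f_gm > 0.1) & (fractions.f_wm > 0.1)
        expect = (
            fractions.f_gm * truth.c_gm
            + fractions.f_wm * truth.c_wm
            + fractions.f_csf * truth.c_csf
        )
        assert np.allclose(conc[mixed], expect[mixed])

    def test_overlapping_eye_rejected(self, coarse_truth):
        bad = PhantomGeometry(
            eyes=(
                Ellipsoid((0.0, 20.0, 0.0), (11.0, 11.0, 11.0)),
                Ellipsoid((30.0, 84.0, -8.0), (11.0, 11.0, 11.0)),
            )
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_phantom(bad, coarse_truth)

    def test_determinism(self, geometry, coarse_truth):
        f1, c1 = generate_phantom(geometry, coarse_truth)
        f2, c2 = generate_phantom(geometry, coarse_truth)
        assert np.array_equal(c1, c2)
        assert np.array_equal(f1.f_gm, f2.f_gm)


class TestPSFKernel:
    def test_normalization_and_symmetry(self):
        ker = build_psf_kernel(56.0, 36.3, (2.0, 2.0, 2.0), kernel_shape=(15, 15, 15))
        assert abs(ker.sum() - 1.0) < 1e-9
        assert np.all(np.isfinite(ker))
        for axis in range(3):
            assert np.allclose(ker, np.flip(ker, axis=axis), atol=1e-12)

    def test_no_decay_limit_is_delta(self):
        ker = build_psf_kernel(1e12, 36.3, (2.0, 2.0, 2.0), kernel_shape=(9, 9, 9))
        assert ker.max() == pytest.approx(1.0, abs=1e-9)

    def test_longer_readout_widens_fwhm(self):
        wide = kernel_fwhm_mm(56.0, 36.3, (2.0, 2.0, 2.0))
        narrow = kernel_fwhm_mm(56.0, 10.0, (2.0, 2.0, 2.0))
        assert wide > narrow

    def test_gaussian_mode_matches_fwhm_and_normalizes(self):
        ker = build_psf_kernel(56.0, 36.3, (2.0, 2.0, 2.0), "gaussian", (15, 15, 15))
        assert abs(ker.sum() - 1.0) < 1e-9
        assert ker.max() == ker[7, 7, 7]

    def test_invalid_t2_rejected(self):
        with pytest.raises(ValueError):
            build_psf_kernel(0.0, 36.3, (2.0, 2.0, 2.0))


class TestBlockAverage:
    def test_hand_mean(self):
        block = np.array([1, 0, 0, 0, 1, 1, 0, 1], dtype=float).reshape(2, 2, 2)
        assert block_average(block, (2, 2, 2))[0, 0, 0] == pytest.approx(0.5)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            block_average(np.zeros((9, 9, 9)), (2, 2, 2))

    @given(st.integers(1, 3), st.integers(1, 3), st.integers(1, 3))
    def test_constant_field_invariance(self, f0, f1, f2):
        field = np.full((6, 6, 6), 3.7)
        out = block_average(field, (f0, f1, f2))
        assert np.allclose(out, 3.7)


class TestAcquisition:
    def test_constant_field_preserved_noiseless(self, geometry, coarse_truth):
        eyes = tuple(m > 0.3 for m in np.zeros((2, 32, 32, 32)))
        const = np.full((64, 64, 64), 42.0)
        vol = simulate_acquisition(const, coarse_truth, eye_regions=eyes)
        assert np.allclose(vol.signal, 42.0 * coarse_truth.gain, rtol=1e-9)

    def test_determinism_with_seed(self, geometry):
        truth = PhantomTruth(hi_res_voxel_mm=(3.0,) * 3, noise_sigma=10.0, seed=7)
        s1 = simulate_study(geometry, truth)
        s2 = simulate_study(geometry, truth)
        assert np.array_equal(s1.raw.signal, s2.raw.signal)

    def test_background_region_size_and_disjointness(self, geometry, coarse_truth):
        study = simulate_study(geometry, coarse_truth)
        assert study.raw.background_region.sum() == 560
        study.raw.validate()

    def test_rician_background_sd_matches_monte_carlo(self, geometry, rng):
        """Sample SD over background voxels ~ the Rician small-signal SD."""
        sigma = 9.0
        truth = PhantomTruth(hi_res_voxel_mm=(3.0,) * 3, noise_sigma=sigma, seed=11)
        study = simulate_study(geometry, truth)
        observed = study.raw.signal[study.raw.background_region].std(ddof=1)
        # independent Monte-Carlo oracle for the zero-signal Rician SD
        draws = np.abs(rng.normal(0, sigma, 10**5) + 1j * rng.normal(0, sigma, 10**5))
        assert observed == pytest.approx(draws.std(ddof=1), rel=0.10)

    def test_corner_box_bounds(self):
        with pytest.raises(ValueError, match="does not fit"):
            background_corner_mask((8, 8, 8), (10, 8, 7))


class TestNoiseScale:
    def test_parenchymal_sigma_is_closed_form(self, geometry, coarse_truth):
        fractions, _ = generate_phantom(geometry, coarse_truth)
        sig = parenchymal_noise_sigma(fractions, coarse_truth, level=0.05)
        v_gm, v_wm = fractions.f_gm.sum(), fractions.f_wm.sum()
        expect = 0.05 * 10.0 * (v_gm * 35 + v_wm * 30) / (v_gm + v_wm)
        assert sig == pytest.approx(expect)


class TestTruthValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"c_gm": -1.0},
            {"noise_sigma": -0.1},
            {"t2_ms": 0.0},
            {"lo_res_voxel_mm": (1.0, 1.0, 1.0)},
            {"noise_model": "poisson"},
        ],
    )
    def test_invalid_truth_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomTruth(**kwargs)
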