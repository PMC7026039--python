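"""Symmetrization, sharpening, bias correction, intermodal registration."""

import dataclasses

import numpy as np
import pytest

from atlasforge.image_core import BinaryMask, Volume, flip_x
from atlasforge.metrics import dice
from atlasforge.phantoms import PhantomSpec, make_phantom
from atlasforge.postprocess import (
    asymmetry_index,
    bias_correct,
    lanczos_warp,
    laplacian_sharpen,
    register_intermodal,
    symmetrize,
)

ASYM_SPEC = PhantomSpec(
    grid_shape=(48, 48, 48),
    modality="MR",
    brain_radii=(16.0, 18.0, 15.0),
    rotation_deg=(0.0, 0.0, 8.0),
    translation_mm=(2.0, 0.0, 0.0),
    seed=5,
)


class TestAsymmetryIndex:
    def test_symmetric_image_zero(self):
        data = np.zeros((8, 6, 6))
        data[3:5] = 1.0
        assert asymmetry_index(Volume(data)) == 0.0

    def test_constant_image_zero(self):
        assert asymmetry_index(Volume(np.full((6, 6, 6), 4.0))) == 0.0

    def test_half_offset_closed_form(self):
        # left half +c on a constant image: |v - flip(v)| = c everywhere,
        # range = c, so the index is 1.0
        data = np.zeros((8, 4, 4))
        data[:4] = 3.0
        assert asymmetry_index(Volume(data)) == pytest.approx(1.0)

    def test_invariant_under_flip(self):
        vol, _, _ = make_phantom(ASYM_SPEC)
        assert asymmetry_index(vol) == pytest.approx(
            asymmetry_index(flip_x(vol)), abs=1e-12
        )


class TestSymmetrize:
    def test_asymmetric_phantom_index_decreases(self):
        vol, _, _ = make_phantom(ASYM_SPEC)
        out = symmetrize(vol)
        assert asymmetry_index(out) < asymmetry_index(vol)

    def test_symmetric_input_unchanged(self):
        spec = dataclasses.replace(
            ASYM_SPEC, rotation_deg=(0, 0, 0), translation_mm=(0, 0, 0),
            ripple_amplitude=0.0,
        )
        vol, _, _ = make_phantom(spec)
        out = symmetrize(vol)
        assert np.abs(out.voxels - vol.voxels).max() < 0.01 * np.ptp(vol.voxels)

    def test_flip_difference_shrinks(self):
        vol, _, _ = make_phantom(ASYM_SPEC)
        out = symmetrize(vol)
        before = np.abs(vol.voxels - vol.voxels[::-1]).mean()
        after = np.abs(out.voxels - out.voxels[::-1]).mean()
        assert after < before

    def test_approximately_idempotent(self):
        vol, _, _ = make_phantom(ASYM_SPEC)
        once = symmetrize(vol)
        twice = symmetrize(once)
        first_reduction = asymmetry_index(vol) - asymmetry_index(once)
        second_change = abs(asymmetry_index(once) - asymmetry_index(twice))
        assert second_change < 0.1 * first_reduction

    def test_resample_mode_exactly_symmetric(self):
        vol, _, _ = make_phantom(ASYM_SPEC)
        out = symmetrize(vol, mode="resample")
        np.testing.assert_allclose(out.voxels, out.voxels[::-1], atol=1e-12)

    def test_bad_mode_rejected(self):
        vol, _, _ = make_phantom(ASYM_SPEC)
        with pytest.raises(ValueError, match="mode"):
            symmetrize(vol, mode="mirror")


class TestLaplacianSharpen:
    def test_constant_image_unchanged(self):
        vol = Volume(np.full((10, 10, 10), 42.0))
        np.testing.assert_array_equal(laplacian_sharpen(vol, 0.5).voxels, vol.voxels)

    def test_zero_strength_identity(self, small_volume):
        out = laplacian_sharpen(small_volume, 0.0)
        np.testing.assert_array_equal(out.voxels, small_volume.voxels)

    def test_step_edge_contrast_and_plateau(self):
        data = np.zeros((24, 8, 8))
        data[12:] = 10.0
        out = laplacian_sharpen(Volume(data), 0.5).voxels
        assert out.max() - out.min() > 10.0  # contrast strictly increased
        np.testing.assert_allclose(out[:10], 0.0, atol=1e-6)  # plateaus kept
        np.testing.assert_allclose(out[14:], 10.0, atol=1e-6)

    def test_global_mean_preserved(self, small_volume):
        out = laplacian_sharpen(small_volume, 0.7)
        assert abs(out.voxels.mean() - small_volume.voxels.mean()) < 1e-3 * abs(
            small_volume.voxels.mean()
        )

    def test_negative_strength_rejected(self, small_volume):
        with pytest.raises(ValueError, match="strength"):
            laplacian_sharpen(small_volume, -0.1)


class TestBiasCorrect:
    # crisp edges (no partial-volume smoothing): piecewise-constant tissue
    # values make field recovery a well-posed oracle
    SPEC = PhantomSpec(
        grid_shape=(48, 48, 48), modality="MR", brain_radii=(16.0, 18.0, 15.0),
        bias_amplitude=0.2, seed=5, edge_smoothing_px=0.0,
    )

    def test_rmse_reduction_on_biased_phantom(self):
        vol, mask, _ = make_phantom(self.SPEC)
        clean, _, _ = make_phantom(dataclasses.replace(self.SPEC, bias_amplitude=0.0))
        out = bias_correct(vol, mask, sigma=10.0)
        m = mask.as_bool()
        rmse0 = np.sqrt(np.mean((vol.voxels[m] - clean.voxels[m]) ** 2))
        rmse1 = np.sqrt(np.mean((out.voxels[m] - clean.voxels[m]) ** 2))
        assert rmse1 <= 0.5 * rmse0

    def test_bias_free_phantom_nearly_unchanged(self):
        vol, mask, _ = make_phantom(dataclasses.replace(self.SPEC, bias_amplitude=0.0))
        out = bias_correct(vol, mask, sigma=10.0)
        m = mask.as_bool()
        rel = np.abs(out.voxels[m] - vol.voxels[m]) / np.abs(vol.voxels[m]).max()
        assert rel.max() < 0.02

    def test_mask_mean_preserved(self):
        vol, mask, _ = make_phantom(self.SPEC)
        out = bias_correct(vol, mask, sigma=10.0)
        m = mask.as_bool()
        assert abs(out.voxels[m].mean() - vol.voxels[m].mean()) < 0.01 * abs(
            vol.voxels[m].mean()
        )

    def test_coefficient_of_variation_reduced(self):
        vol, mask, _ = make_phantom(self.SPEC)
        out = bias_correct(vol, mask, sigma=10.0)
        m = mask.as_bool()
        # CV over parenchyma-like voxels (ventricle excluded by intensity)
        par0 = vol.voxels[m][vol.voxels[m] > 50]
        par1 = out.voxels[m][out.voxels[m] > 50]
        assert par1.std() / par1.mean() < par0.std() / par0.mean()

    def test_constant_image_unchanged(self):
        vol = Volume(np.full((12, 12, 12), 5.0))
        mask = BinaryMask(np.ones((12, 12, 12), dtype=np.uint8))
        out = bias_correct(vol, mask)
        np.testing.assert_allclose(out.voxels, 5.0, atol=1e-6)

    def test_empty_mask_rejected(self, small_volume):
        mask = BinaryMask(np.zeros(small_volume.shape, dtype=np.uint8))
        with pytest.raises(ValueError, match="mask"):
            bias_correct(small_volume, mask)


class TestLanczosWarp:
    def test_zero_field_near_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16))
        out = lanczos_warp(img, np.zeros((16, 16, 2)))
        np.testing.assert_allclose(out, img, atol=1e-9)

    def test_flat_region_stays_flat(self):
        img = np.full((16, 16, 16), 7.0)
        disp = np.full((16, 16, 16, 3), 0.4)
        out = lanczos_warp(img, disp)
        np.testing.assert_allclose(out[2:-2, 2:-2, 2:-2], 7.0, atol=1e-9)


class TestRegisterIntermodal:
    def test_remapped_copy_near_identity(self):
        spec = PhantomSpec(
            grid_shape=(40, 40, 40), modality="CT", brain_radii=(13.0, 15.0, 12.0),
            seed=5,
        )
        ct, _, _ = make_phantom(spec)
        # bijective HU -> MR-like lookup; MI is invariant to such remaps
        mr_like = Volume(
            np.interp(ct.voxels, [-1000, 20, 40, 1000], [0, 80, 120, 30]),
            modality="MR",
        )
        res, warped = register_intermodal(mr_like, ct)
        mean_disp = np.sqrt((res.forward.vectors**2).sum(axis=-1)).mean()
        assert mean_disp < 1.0

    def test_shared_geometry_mask_overlap(self):
        base = dict(grid_shape=(40, 40, 40), brain_radii=(13.0, 15.0, 12.0), seed=8)
        mr, mr_mask, _ = make_phantom(PhantomSpec(modality="MR", **base))
        ct, ct_mask, _ = make_phantom(PhantomSpec(modality="CT", **base))
        res, warped = register_intermodal(mr, ct)
        warped_mask = warped.voxels > -500.0
        assert dice(warped_mask, mr_mask.as_bool()) > 0.9

    def test_grid_mismatch_rejected(self):
        a = Volume(np.zeros((8, 8, 8)))
        b = Volume(np.zeros((8, 8, 10)), modality="CT")
        with pytest.raises(ValueError, match="grid"):
            register_intermodal(a, b)
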