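"""Registration engine: parameter recovery, diffeomorphism guarantees,
field inversion and transform algebra."""

import dataclasses

import numpy as np
import pytest

from atlasforge.image_core import DisplacementField, compose_disp, exp_velocity, warp_array
from atlasforge.metrics import dice, jacobian_determinant
from atlasforge.phantoms import PhantomSpec, make_phantom
from atlasforge.registration import (
    AffineTransform,
    RegistrationParams,
    invert_field,
    mutual_information,
    register_affine,
    register_demons_array,
    register_diffeomorphic,
    register_rigid,
    remove_rigid,
)

from conftest import gaussian_bump_field, smooth_disk

BASE_SPEC = PhantomSpec(
    grid_shape=(40, 40, 40), modality="MR", brain_radii=(13.0, 15.0, 12.0), seed=3
)


def phantom_pair(**moving_changes):
    fixed, _, _ = make_phantom(BASE_SPEC)
    moving, _, _ = make_phantom(dataclasses.replace(BASE_SPEC, **moving_changes))
    return fixed, moving


class TestAffineTransform:
    def test_identity_roundtrip(self):
        t = AffineTransform.identity(3)
        arr = np.random.default_rng(0).random((8, 8, 8))
        np.testing.assert_allclose(t.apply_to_array(arr), arr, atol=1e-12)

    def test_inverse_compose_is_identity(self):
        t = AffineTransform(np.diag([1.2, 0.9, 1.0]), np.array([2.0, -1.0, 0.5]))
        c = t.compose(t.inverse())
        np.testing.assert_allclose(c.linear, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(c.translation, 0.0, atol=1e-12)

    def test_singular_rejected(self):
        with pytest.raises(ValueError, match="invertible"):
            AffineTransform(np.zeros((3, 3)), np.zeros(3))


class TestRemoveRigid:
    def test_pure_rotation_becomes_identity(self):
        a = np.deg2rad(20)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        out = remove_rigid(AffineTransform(rot, np.array([3.0, -2.0])))
        np.testing.assert_allclose(out.linear, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(out.translation, 0.0)

    def test_pure_scaling_unchanged(self):
        s = np.diag([1.3, 0.8, 1.1])
        out = remove_rigid(AffineTransform(s, np.array([1.0, 1.0, 1.0])))
        np.testing.assert_allclose(out.linear, s, atol=1e-12)
        np.testing.assert_allclose(out.translation, 0.0)

    def test_rotation_times_scale_polar_oracle(self):
        a = np.deg2rad(15)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        t = AffineTransform(rot @ (1.2 * np.eye(2)), np.zeros(2))
        out = remove_rigid(t)
        np.testing.assert_allclose(out.linear, out.linear.T, atol=1e-9)
        np.testing.assert_allclose(np.linalg.eigvalsh(out.linear), [1.2, 1.2], atol=1e-6)


class TestParametricRecovery:
    def test_identity_case(self):
        fixed, _, _ = make_phantom(BASE_SPEC)
        t = register_rigid(fixed, fixed)
        assert np.linalg.norm(t.translation) < 0.2
        np.testing.assert_allclose(t.linear, np.eye(3), atol=0.01)

    def test_translation_recovery(self):
        fixed, moving = phantom_pair(translation_mm=(4.0, -2.0, 0.0))
        t = register_rigid(fixed, moving)
        np.testing.assert_allclose(t.translation, [4.0, -2.0, 0.0], atol=0.5)

    def test_rotation_recovery(self):
        fixed, moving = phantom_pair(rotation_deg=(0.0, 0.0, 10.0))
        t = register_rigid(fixed, moving)
        angle = np.degrees(np.arctan2(t.linear[1, 0], t.linear[0, 0]))
        assert abs(angle - 10.0) < 1.0

    def test_isotropic_scale_recovery(self):
        radii = tuple(1.1 * r for r in BASE_SPEC.brain_radii)
        fixed, moving = phantom_pair(brain_radii=radii)
        t = register_affine(fixed, moving)
        svals = np.linalg.svd(t.linear, compute_uv=False)
        np.testing.assert_allclose(svals, 1.1, rtol=0.02)

    def test_anisotropic_scale_recovery(self):
        radii = tuple(s * r for s, r in zip((1.1, 0.9, 1.0), BASE_SPEC.brain_radii))
        fixed, moving = phantom_pair(brain_radii=radii)
        t = register_affine(fixed, moving)
        # recover per-axis stretch from the symmetric part
        stretch = remove_rigid(t).linear
        recovered = np.sort(np.diag(stretch))[::-1]
        np.testing.assert_allclose(recovered, [1.1, 1.0, 0.9], rtol=0.03)

    @pytest.mark.parametrize("seed", range(5))
    def test_seeded_random_pose_recovery(self, seed):
        rng = np.random.default_rng(seed)
        trans = tuple(rng.uniform(-3, 3, 3))
        fixed, moving = phantom_pair(translation_mm=trans)
        t = register_rigid(fixed, moving)
        np.testing.assert_allclose(t.translation, trans, atol=0.5)


class TestDiffeomorphic:
    def test_identical_inputs_near_zero_field(self):
        fixed, _, _ = make_phantom(BASE_SPEC)
        res = register_diffeomorphic(fixed, fixed)
        assert res.forward.max_magnitude() < 0.2

    def test_translated_disk_displacement(self):
        f = smooth_disk((64, 64), (32, 32), 10)
        m = smooth_disk((64, 64), (35, 32), 10)
        vel, _, _ = register_demons_array(f, m, RegistrationParams.fast_2d())
        fwd = exp_velocity(vel)
        inside = smooth_disk((64, 64), (32, 32), 8) > 50
        mean_disp = fwd[inside].mean(axis=0)
        assert abs(mean_disp[0] - 3.0) < 0.5
        assert abs(mean_disp[1]) < 0.5
        assert jacobian_determinant(fwd).min() > 0

    def test_expanding_disk_dice(self):
        f = smooth_disk((48, 48, 48), (24, 24, 24), 12)
        m = smooth_disk((48, 48, 48), (24, 24, 24), 8)
        res = register_diffeomorphic(f, m)
        warped = warp_array(m, res.forward.vectors)
        assert dice(warped > 50, f > 50) > 0.95
        assert jacobian_determinant(res.forward).min() > 0

    def test_forward_inverse_residual(self):
        f = smooth_disk((48, 48, 48), (24, 24, 24), 12)
        m = smooth_disk((48, 48, 48), (22, 24, 24), 10)
        res = register_diffeomorphic(f, m)
        residual = compose_disp(res.forward.vectors, res.inverse.vectors)
        assert np.sqrt((residual**2).sum(axis=-1)).max() < 0.5

    def test_metric_trace_monotone_final_level(self):
        f = smooth_disk((48, 48), (24, 24), 10)
        m = smooth_disk((48, 48), (27, 24), 10)
        _, trace, _ = register_demons_array(f, m, RegistrationParams.fast_2d())
        final = trace[-8:]
        assert all(b <= a * 1.05 for a, b in zip(final, final[1:]))

    @pytest.mark.parametrize("seed", range(4))
    def test_jacobian_positive_on_random_phantom_pairs(self, seed):
        rng = np.random.default_rng(seed)
        spec = dataclasses.replace(BASE_SPEC, grid_shape=(32, 32, 32),
                                   brain_radii=(10.0, 12.0, 9.0), seed=seed)
        fixed, _, _ = make_phantom(spec)
        moving, _, _ = make_phantom(
            dataclasses.replace(
                spec,
                brain_radii=tuple(r * rng.uniform(0.9, 1.1) for r in spec.brain_radii),
                translation_mm=tuple(rng.uniform(-2, 2, 3)),
            )
        )
        res = register_diffeomorphic(fixed, moving)
        assert jacobian_determinant(res.forward).min() > 0
        assert jacobian_determinant(res.inverse).min() > 0

    def test_symmetry_of_direction(self):
        f = smooth_disk((48, 48, 48), (24, 24, 24), 12)
        m = smooth_disk((48, 48, 48), (24, 24, 24), 8)
        ab = register_diffeomorphic(f, m)
        ba = register_diffeomorphic(m, f)
        comp = compose_disp(ab.forward.vectors, ba.forward.vectors)
        assert np.sqrt((comp**2).sum(axis=-1)).max() < 1.0


class TestInvertField:
    def test_zero_field(self):
        f = DisplacementField.zero((12, 12, 12))
        np.testing.assert_array_equal(invert_field(f).vectors, 0.0)

    def test_constant_translation(self):
        vec = np.zeros((24, 24, 2))
        vec[..., 0] = 2.0
        inv = invert_field(DisplacementField(vec))
        interior = inv.vectors[6:-6, 6:-6]
        np.testing.assert_allclose(interior[..., 0], -2.0, atol=0.05)

    def test_gaussian_bump_residual(self):
        f = DisplacementField(gaussian_bump_field((32, 32), amplitude=2.0))
        inv = invert_field(f)
        residual = compose_disp(f.vectors, inv.vectors)
        assert np.sqrt((residual**2).sum(axis=-1)).max() < 0.5


class TestMutualInformation:
    def test_discriminates_remapped_signal_from_noise(self):
        # binned MI loses some information under a non-linear remap, but a
        # monotone remap of the same signal must still score far above an
        # independent image
        rng = np.random.default_rng(0)
        a = rng.normal(size=(24, 24, 24))
        remapped = np.exp(a)
        independent = rng.normal(size=(24, 24, 24))
        assert mutual_information(a, remapped) > 10 * mutual_information(
            a, independent
        )

    def test_independent_images_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(24, 24, 24))
        b = rng.normal(size=(24, 24, 24))
        assert mutual_information(a, b) < 0.1
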