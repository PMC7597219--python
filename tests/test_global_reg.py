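import numpy as np
import pytest

import hetmap
from hetmap.core import AffineMap, BinaryMask, DisplacementField
from hetmap.global_reg import (AffineOptConfig, DemonsConfig, compose_fields,
                               demons_force, exponentiate_field,
                               register_affine, register_demons, warp,
                               warp_affine)
from hetmap.masking import rough_mask
from hetmap.prealign import prealign


class TestWarp:
    def test_zero_field_is_identity(self, rng):
        img = rng.random((32, 40))
        out = warp(img, DisplacementField.zero((32, 40)))
        np.testing.assert_allclose(out, img)

    def test_constant_field_shifts_a_ramp(self):
        ramp = np.tile(np.arange(40, dtype=float), (30, 1))
        field = DisplacementField(np.ones((30, 40)), np.zeros((30, 40)))
        out = warp(ramp, field)
        np.testing.assert_allclose(out[:, :-1], ramp[:, :-1] + 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            warp(np.zeros((4, 4)), DisplacementField.zero((5, 5)))

    def test_inverse_composition_restores_interior(self, rng):
        """Warping forward then through the numerically composed inverse is
        close to the identity in the interior for a small smooth field."""
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.random((64, 64)) * 255, 3.0)
        u = gaussian_filter(rng.normal(0, 2.0, (64, 64)), 8.0)
        v = gaussian_filter(rng.normal(0, 2.0, (64, 64)), 8.0)
        d = DisplacementField(u, v)
        # fixed-point inversion of the backward map
        inv = DisplacementField(-u, -v)
        for _ in range(20):
            w = warp(np.stack([d.u, d.v], -1), inv)
            inv = DisplacementField(-w[:, :, 0], -w[:, :, 1])
        round_trip = warp(warp(img, d), inv)
        interior = np.s_[8:-8, 8:-8]
        err = np.abs(round_trip[interior] - img[interior])
        assert np.quantile(err, 0.95) < 1.0


class TestRegisterAffine:
    def test_identical_masks_give_identity(self, default_stack):
        m = rough_mask(default_stack.fixed)
        res = register_affine(m, m)
        np.testing.assert_allclose(res.transform.matrix, np.eye(2), atol=1e-3)
        np.testing.assert_allclose(res.transform.offset, 0, atol=1e-2)

    def test_scale_recovery(self, default_stack):
        """A mask scaled by 1.10 about its centroid is recovered to +/-0.02."""
        m = rough_mask(default_stack.fixed)
        rows, cols = np.nonzero(m.values)
        c = np.array([cols.mean(), rows.mean()])
        fwd = AffineMap(np.eye(2) / 1.10, c - c / 1.10)  # backward map of x1.10
        scaled = warp_affine(m, fwd)
        res = register_affine(m, scaled)
        # the backward sampling map must magnify fixed coordinates by 1.10
        recovered_scale = np.sqrt(abs(np.linalg.det(res.transform.matrix)))
        assert recovered_scale == pytest.approx(1.10, abs=0.02)

    def test_final_mse_never_exceeds_initial(self, rigid_only_stack):
        stack = rigid_only_stack
        fm = rough_mask(stack.fixed)
        mm = rough_mask(stack.sections[1])
        res = register_affine(fm, mm)
        assert res.final_mse <= res.initial_mse

    def test_translation_equivariance(self, default_stack):
        """Translating both masks by the same integer vector leaves the
        recovered linear part unchanged."""
        m = rough_mask(default_stack.fixed)
        fwd = AffineMap(np.array([[1.05, 0.02], [-0.01, 0.97]]), np.array([3.0, -2.0]))
        moving = warp_affine(m, fwd)
        res1 = register_affine(m, moving)
        shift = lambda v: np.roll(np.roll(v, 5, axis=0), 5, axis=1)
        res2 = register_affine(BinaryMask(shift(m.values)),
                               BinaryMask(shift(moving.values)))
        np.testing.assert_allclose(res1.transform.matrix, res2.transform.matrix,
                                   atol=0.02)


class TestDemonsForce:
    def test_zero_on_identical_images(self, rng):
        img = rng.random((20, 20))
        f = demons_force(img, img)
        assert np.abs(f.u).max() == 0.0
        assert np.abs(f.v).max() == 0.0

    def test_unit_case_gives_half(self):
        """Im - If = 1 with gradient (1, 0) yields v = (0.5, 0)."""
        fixed = np.tile(np.arange(5, dtype=float), (5, 1))
        moving = fixed + 1.0
        f = demons_force(fixed, moving)
        assert f.u[2, 2] == pytest.approx(0.5)
        assert f.v[2, 2] == pytest.approx(0.0)

    def test_magnitude_bounded_by_half(self, rng):
        for _ in range(5):
            a = rng.random((30, 30))
            b = rng.random((30, 30))
            assert demons_force(a, b).magnitude().max() <= 0.5 + 1e-12


class TestRegisterDemons:
    def test_identical_masks_give_tiny_field(self, default_stack):
        m = rough_mask(default_stack.fixed)
        field = register_demons(m, m)
        assert field.magnitude().max() < 0.1

    def test_ssd_at_least_halved(self, demons_run):
        fm, aligned, field = demons_run
        f = fm.values.astype(float)
        m0 = aligned.values.astype(float)
        initial = np.sum((m0 - f) ** 2)
        final = np.sum((warp(m0, field) - f) ** 2)
        assert final <= 0.5 * initial

    def test_field_is_diffeomorphic(self, demons_run):
        _, _, field = demons_run
        jac = field.jacobian_determinant()
        assert (jac > 0).mean() >= 0.999


class TestPersistence:
    def test_field_round_trip_tiff(self, tmp_path, rng):
        from hetmap.global_reg import load_field, save_field

        d = DisplacementField(rng.normal(0, 3, (20, 24)),
                              rng.normal(0, 3, (20, 24)))
        save_field(tmp_path / "f.tiff", d)
        back = load_field(tmp_path / "f.tiff")
        np.testing.assert_allclose(back.u, d.u, atol=1e-5)
        np.testing.assert_allclose(back.v, d.v, atol=1e-5)

    def test_affine_round_trip_json(self, tmp_path):
        from hetmap.global_reg import load_affine, save_affine

        a = AffineMap(np.array([[1.1, 0.02], [-0.03, 0.95]]), np.array([4.5, -2.0]))
        save_affine(tmp_path / "a.json", a)
        back = load_affine(tmp_path / "a.json")
        np.testing.assert_array_equal(back.matrix, a.matrix)
        np.testing.assert_array_equal(back.offset, a.offset)


class TestFieldAlgebra:
    def test_exponentiated_field_has_positive_jacobian(self, rng):
        from scipy.ndimage import gaussian_filter

        u = gaussian_filter(rng.normal(0, 3.0, (48, 48)), 4.0)
        v = gaussian_filter(rng.normal(0, 3.0, (48, 48)), 4.0)
        exp = exponentiate_field(DisplacementField(u, v))
        assert (exp.jacobian_determinant() > 0).mean() > 0.999

    def test_compose_with_zero_is_identity(self, rng):
        d = DisplacementField(rng.random((16, 16)), rng.random((16, 16)))
        z = DisplacementField.zero((16, 16))
        out = compose_fields(d, z)
        np.testing.assert_allclose(out.u, d.u)
        np.testing.assert_allclose(out.v, d.v)
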