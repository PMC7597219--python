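import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hetmap
from hetmap.core import BinaryMask
from hetmap.local_reg import (BSplineGrid, FFDConfig, bending_energy,
                              bspline_basis, ffd_displacement,
                              grid_to_field, register_ffd, similarity_log,
                              LOG_EPS, _bending_energy_grad)
from hetmap.masking import rough_mask
from hetmap.synthetic import deform_section


def brute_force_displacement(grid: BSplineGrid, point):
    """Oracle: sum over ALL control points with explicitly computed cubic
    B-spline weights (uniform B-spline centered at each control point)."""
    def b3(t):
        t = abs(t)
        if t < 1:
            return (4 - 6 * t ** 2 + 3 * t ** 3) / 6
        if t < 2:
            return (2 - t) ** 3 / 6
        return 0.0

    x, y = point
    nx, ny = grid.n_points
    out = np.zeros(2)
    for ii in range(nx):
        for jj in range(ny):
            cx = grid.origin[0] + ii * grid.spacing[0]
            cy = grid.origin[1] + jj * grid.spacing[1]
            w = b3((x - cx) / grid.spacing[0]) * b3((y - cy) / grid.spacing[1])
            out += w * grid.phi[ii, jj]
    return out


class TestBasis:
    def test_values_at_zero(self):
        np.testing.assert_allclose(bspline_basis(0.0),
                                   (1 / 6, 4 / 6, 1 / 6, 0.0), atol=1e-15)

    def test_values_at_half(self):
        np.testing.assert_allclose(bspline_basis(0.5),
                                   (0.125 / 6, 2.875 / 6, 2.875 / 6, 0.125 / 6),
                                   atol=1e-15)

    @given(st.floats(min_value=0.0, max_value=1.0, exclude_max=True))
    @settings(max_examples=200, deadline=None)
    def test_partition_of_unity(self, u):
        assert abs(sum(bspline_basis(u)) - 1.0) < 1e-12

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            bspline_basis(1.0)


class TestDisplacement:
    def _grid(self, seed=0, shape=(120, 140), spacing=(20.0, 25.0)):
        g = BSplineGrid.for_shape(shape, spacing)
        g.phi = np.random.default_rng(seed).uniform(-4, 4, g.phi.shape)
        return g

    def test_zero_grid_gives_zero(self):
        g = BSplineGrid.for_shape((100, 100), (25.0, 25.0))
        pts = np.array([[0.0, 0.0], [50.0, 30.0], [99.0, 99.0]])
        np.testing.assert_array_equal(ffd_displacement(g, pts), 0.0)

    def test_constant_grid_gives_constant(self, rng):
        g = BSplineGrid.for_shape((100, 100), (25.0, 25.0))
        g.phi[:, :, 0] = 3.25
        g.phi[:, :, 1] = -1.5
        pts = rng.uniform(0, 99, (50, 2))
        np.testing.assert_allclose(ffd_displacement(g, pts),
                                   np.tile([3.25, -1.5], (50, 1)), atol=1e-12)

    def test_matches_all_control_point_oracle(self, rng):
        g = self._grid()
        pts = rng.uniform(5, 95, (20, 2))
        fast = ffd_displacement(g, pts)
        slow = np.array([brute_force_displacement(g, p) for p in pts])
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_single_control_point_has_local_support(self):
        """One displaced control point only affects its 4-spacing square."""
        spacing = 20.0
        g = BSplineGrid.for_shape((160, 160), (spacing, spacing))
        g.phi[5, 5, 0] = 10.0  # control point at (80, 80)
        field = grid_to_field(g, (160, 160))
        moved = (np.abs(field.u) > 0) | (np.abs(field.v) > 0)
        yy, xx = np.nonzero(moved)
        assert xx.min() > 80 - 2 * spacing and xx.max() < 80 + 2 * spacing
        assert yy.min() > 80 - 2 * spacing and yy.max() < 80 + 2 * spacing

    def test_point_outside_domain_rejected(self):
        g = BSplineGrid.for_shape((50, 50), (10.0, 10.0))
        with pytest.raises(ValueError):
            ffd_displacement(g, np.array([[500.0, 10.0]]))


class TestGridPersistence:
    def test_json_round_trip(self, tmp_path, rng):
        from hetmap.local_reg import load_grid, save_grid

        g = BSplineGrid.for_shape((80, 80), (20.0, 20.0))
        g.phi = rng.normal(0, 3, g.phi.shape)
        save_grid(tmp_path / "g.json", g)
        back = load_grid(tmp_path / "g.json")
        np.testing.assert_array_equal(back.phi, g.phi)
        assert back.spacing == g.spacing and back.origin == g.origin


class TestSimilarity:
    def test_identical_images_hit_epsilon_floor(self, rng):
        img = rng.random((30, 30))
        roi = BinaryMask(np.ones((30, 30), bool))
        assert similarity_log(img, img, roi) == pytest.approx(np.log(LOG_EPS))

    def test_unit_difference_is_near_zero(self):
        roi = BinaryMask(np.ones((10, 10), bool))
        a = np.zeros((10, 10))
        assert similarity_log(a, a + 1.0, roi) == pytest.approx(0.0, abs=1e-5)

    def test_alignment_reduces_similarity(self, default_stack):
        """Undoing the known warp lowers the log-difference metric."""
        from hetmap.local_reg import _to_gray
        from hetmap.global_reg import warp
        from hetmap.synthetic import forward_map

        fixed = default_stack.fixed
        moving = default_stack.sections[1]
        truth = default_stack.ground_truth[1]
        roi = rough_mask(fixed)
        fwd = forward_map(truth.rigid, truth.grid, fixed.shape)
        rows, cols = fixed.shape
        yy, xx = np.mgrid[0:rows, 0:cols]
        pts = np.stack([xx.ravel(), yy.ravel()], 1).astype(float)
        mapped = fwd(pts)
        from hetmap.core import DisplacementField
        d = DisplacementField((mapped[:, 0] - pts[:, 0]).reshape(rows, cols),
                              (mapped[:, 1] - pts[:, 1]).reshape(rows, cols))
        undone = warp(_to_gray(moving), d, fill=1.0)
        before = similarity_log(_to_gray(fixed), _to_gray(moving), roi)
        after = similarity_log(_to_gray(fixed), undone, roi)
        assert after < before

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            similarity_log(np.zeros((5, 5)), np.zeros((5, 5)),
                           BinaryMask(np.zeros((5, 5), bool)))


class TestBendingEnergy:
    def test_zero_and_constant_grids_have_no_energy(self):
        g = BSplineGrid.for_shape((100, 100), (25.0, 25.0))
        assert bending_energy(g) == 0.0
        g.phi[:] = 7.0
        assert bending_energy(g) == pytest.approx(0.0, abs=1e-20)

    def test_affine_grid_has_no_energy(self):
        g = BSplineGrid.for_shape((100, 100), (25.0, 25.0))
        for i in range(g.n_points[0]):
            g.phi[i, :, 0] = 0.3 * i  # linear in x -> zero second derivatives
        assert bending_energy(g) == pytest.approx(0.0, abs=1e-18)

    def test_quadratic_scaling(self, rng):
        g = BSplineGrid.for_shape((100, 100), (25.0, 25.0))
        g.phi = rng.normal(0, 3, g.phi.shape)
        e1 = bending_energy(g)
        g2 = BSplineGrid(3.0 * g.phi, g.spacing, g.origin)
        assert bending_energy(g2) == pytest.approx(9.0 * e1, rel=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        g = BSplineGrid.for_shape((80, 80), (20.0, 20.0))
        g.phi = rng.normal(0, 2, g.phi.shape)
        _, grad = _bending_energy_grad(g)
        for _ in range(5):
            i = rng.integers(g.phi.shape[0])
            j = rng.integers(g.phi.shape[1])
            c = rng.integers(2)
            h = 1e-5
            gp = BSplineGrid(g.phi.copy(), g.spacing, g.origin)
            gp.phi[i, j, c] += h
            gm = BSplineGrid(g.phi.copy(), g.spacing, g.origin)
            gm.phi[i, j, c] -= h
            fd = (bending_energy(gp) - bending_energy(gm)) / (2 * h)
            assert grad[i, j, c] == pytest.approx(fd, rel=1e-5, abs=1e-12)


class TestRegisterFFD:
    def test_identical_sections_give_near_zero_grid(self, default_stack):
        fixed = default_stack.fixed
        grid, _ = register_ffd(fixed, fixed, roi=rough_mask(fixed))
        assert np.abs(grid.phi).max() < 0.5

    def test_huge_lambda_freezes_the_grid(self, aligned_pair):
        """On an already-aligned pair (the FFD's operating regime) an
        overwhelming bending penalty pins the grid at zero."""
        fixed = aligned_pair.fixed
        moving = aligned_pair.sections[1]
        cfg = FFDConfig(lambda_smooth=1e6)
        grid, _ = register_ffd(fixed, moving, cfg, roi=rough_mask(fixed))
        assert np.abs(grid.phi).max() < 0.1

    def test_known_warp_halves_landmark_error(self):
        """A pair differing by an amplitude-8 control grid: the fitted FFD
        at least halves the median landmark error."""
        cfg = hetmap.FixtureConfig(seed=11, n_sections=2, rigid_range=(0, 0),
                                   warp_amplitude=0.0, artifact_rates={})
        stack = hetmap.make_stack(cfg)
        fixed = stack.fixed
        true_grid = BSplineGrid.for_shape(fixed.shape, (50.0, 50.0))
        true_grid.phi = np.random.default_rng(2).uniform(-8, 8, true_grid.phi.shape)
        moving, rec = deform_section(stack.sections[1], (0.0, 0.0, 0.0),
                                     true_grid, None, seed=0)
        grid, cost = register_ffd(fixed, moving, roi=rough_mask(fixed))
        lm = fixed.landmarks.points
        true_pos = rec["landmarks"].points
        before = np.median(np.linalg.norm(lm - true_pos, axis=1))
        after = np.median(np.linalg.norm(
            lm + ffd_displacement(grid, lm) - true_pos, axis=1))
        assert after <= 0.5 * before
        assert cost.total <= np.log(1.0)  # sanity: cost is a real log mean
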