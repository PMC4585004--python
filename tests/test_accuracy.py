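"""Error vectors, the affine target-to-endpoint map, distortion grids."""

import numpy as np
import pytest

import avloc
from avloc import (DistributionSummary, Target, build_target_grid,
                   distortion_grid, error_vector, fit_affine)


def _summary(mu_x, mu_y):
    return DistributionSummary(mu_x, mu_y, 1.0, 1.0, 0.0, n=10)


class TestErrorVector:
    def test_pure_undershoot(self):
        ev = error_vector(_summary(8.8, 0.0), Target(0, 10.0, 0.0))
        assert ev.r == pytest.approx(1.2)
        assert ev.alpha_deg == pytest.approx(180.0)
        assert ev.circular_deviation_deg == pytest.approx(180.0)
        assert ev.axial_deviation_deg == pytest.approx(0.0)

    def test_perfect_accuracy_flags_direction_undefined(self):
        ev = error_vector(_summary(10.0, 0.0), Target(0, 10.0, 0.0))
        assert ev.r == 0.0
        assert ev.alpha_deg is None
        assert ev.circular_deviation_deg is None

    def test_central_target_has_no_deviation(self):
        ev = error_vector(_summary(1.0, 0.0), Target(0, 0.0, 0.0))
        assert ev.target_direction_deg is None
        assert ev.circular_deviation_deg is None

    def test_calibrated_visual_bias_fraction(self):
        """The visual bias field undershoots by roughly 11% of eccentricity."""
        cfg = avloc.default_config(seed=0)
        field = avloc.ground_truth_field(cfg, "V")
        field = field[(field["az_deg"].abs() <= 20)
                      & (field[["az_deg", "el_deg"]].abs().sum(axis=1) > 0)]
        ecc = np.hypot(field["az_deg"], field["el_deg"])
        r = np.hypot(field["mu_x"] - field["az_deg"],
                     field["mu_y"] - field["el_deg"])
        assert 0.08 <= (r / ecc).mean() <= 0.15

    def test_calibrated_bias_points_inward(self):
        """Visual and bimodal error vectors oppose the target direction."""
        cfg = avloc.default_config(seed=0)
        for cond in ("V", "VA"):
            field = avloc.ground_truth_field(cfg, cond)
            field = field[field[["az_deg", "el_deg"]].abs().sum(axis=1) > 0]
            dx = field["mu_x"] - field["az_deg"]
            dy = field["mu_y"] - field["el_deg"]
            inward = -np.stack([field["az_deg"], field["el_deg"]], axis=1)
            dots = (np.stack([dx, dy], axis=1) * inward).sum(axis=1)
            norms = np.hypot(dx, dy) * np.hypot(*inward.T)
            keep = norms > 1e-9
            # angle to the anti-target direction within 90 deg
            assert (dots[keep] / norms[keep] > 0).all()


class TestAffineFit:
    def _grid_targets(self):
        return build_target_grid(5, 5, 10.0).positions

    def test_identity_map(self):
        t = self._grid_targets()
        m = fit_affine(t, t)
        assert np.allclose(m.linear, np.eye(2), atol=1e-12)
        assert np.allclose(m.translation, 0, atol=1e-12)
        assert m.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_pure_isotropic_contraction(self):
        t = self._grid_targets()
        m = fit_affine(t, 0.881 * t)
        assert m.scale_x == pytest.approx(0.881)
        assert m.scale_y == pytest.approx(0.881)
        assert m.rotation_deg == pytest.approx(0.0, abs=1e-9)
        assert m.shear == pytest.approx(0.0, abs=1e-12)

    def test_decomposition_recomposes(self, rng):
        t = self._grid_targets()
        linear = np.array([[0.9, 0.12], [-0.08, 0.85]])
        m = fit_affine(t, t @ linear.T + [1.0, -2.0])
        assert np.allclose(m.recompose(), m.linear, atol=1e-10)
        assert np.allclose(m.linear, linear, atol=1e-10)

    def test_noisy_recovery_within_3_standard_errors(self, rng):
        t = self._grid_targets()
        linear = np.array([[0.88, 0.05], [-0.03, 0.92]])
        translation = np.array([0.4, -0.8])
        sigma = 0.3
        clean = t @ linear.T + translation
        m = fit_affine(t, clean + rng.normal(0, sigma, clean.shape))
        design = np.column_stack([t, np.ones(len(t))])
        se = sigma * np.sqrt(np.diag(np.linalg.inv(design.T @ design)))
        for row in range(2):
            assert abs(m.linear[row, 0] - linear[row, 0]) < 3 * se[0]
            assert abs(m.linear[row, 1] - linear[row, 1]) < 3 * se[1]
            assert abs(m.translation[row] - translation[row]) < 3 * se[2]

    def test_translation_equivariance(self):
        t = self._grid_targets()
        c = 0.9 * t + [0.3, 0.1]
        shift = np.array([2.5, -1.0])
        m0, m1 = fit_affine(t, c), fit_affine(t, c + shift)
        assert np.allclose(m1.linear, m0.linear, atol=1e-12)
        assert np.allclose(m1.translation, m0.translation + shift, atol=1e-10)

    def test_zero_residual_iff_exact_affine_image(self, rng):
        t = self._grid_targets()
        exact = t @ np.array([[0.8, 0.1], [0.0, 0.9]]).T + [1, 1]
        assert fit_affine(t, exact).rms_residual < 1e-10
        warped = exact.copy()
        warped[0] += [0.5, 0.0]
        assert fit_affine(t, warped).rms_residual > 1e-3

    def test_collinear_targets_rejected(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(np.linalg.LinAlgError):
            fit_affine(line, line)


class TestDistortionGrid:
    def _grid(self):
        return build_target_grid(3, 3, 10.0)

    def test_identity_centroids(self):
        grid = self._grid()
        cents = {t.id: np.array([t.azimuth, t.elevation]) for t in grid}
        d = distortion_grid(cents, grid)
        assert len(d.edges) == 12  # 3x3 grid: 2*3 + 2*3 edges
        assert np.allclose(d.edges["length_ratio"], 1.0)
        assert not d.fold_over

    def test_uniform_contraction_scales_all_ratios(self):
        grid = self._grid()
        g = 0.7
        cents = {t.id: g * np.array([t.azimuth, t.elevation]) for t in grid}
        d = distortion_grid(cents, grid)
        assert np.allclose(d.edges["length_ratio"], g)
        assert not d.fold_over

    def test_swapped_neighbours_raise_fold_over(self):
        grid = self._grid()
        cents = {t.id: np.array([t.azimuth, t.elevation]) for t in grid}
        a = next(t.id for t in grid if (t.azimuth, t.elevation) == (0, 0))
        b = next(t.id for t in grid if (t.azimuth, t.elevation) == (10, 0))
        cents[a], cents[b] = cents[b], cents[a]
        assert distortion_grid(cents, grid).fold_over

    def test_missing_centroid_skips_and_reports(self):
        grid = self._grid()
        cents = {t.id: np.array([t.azimuth, t.elevation]) for t in grid}
        dropped = next(t.id for t in grid if (t.azimuth, t.elevation) == (0, 0))
        del cents[dropped]
        d = distortion_grid(cents, grid)
        assert len(d.missing_edges) == 4  # centre target touches 4 edges
        assert len(d.edges) == 8
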