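"""MLE fusion: scalar and full-covariance rules against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import avloc
from avloc import (DistributionSummary, fuse_1d, fuse_gaussians_2d,
                   grid_product_oracle, predict_bimodal_field)


def _rand_pd_summary(rng, mean_scale=2.0, var_range=(0.3, 4.0)):
    a = rng.uniform(*var_range, size=2)
    rho = rng.uniform(-0.8, 0.8)
    cov = np.array([
        [a[0], rho * np.sqrt(a[0] * a[1])],
        [rho * np.sqrt(a[0] * a[1]), a[1]],
    ])
    mean = rng.uniform(-mean_scale, mean_scale, size=2)
    return DistributionSummary.from_moments(mean, cov)


class TestFuse1D:
    def test_symmetric_case(self):
        var, w_v, w_a, r = fuse_1d(0.0, 2.0, 3.0, 3.0)
        assert w_v == w_a == 0.5
        assert var == pytest.approx(1.5)
        assert r == pytest.approx(1.0)

    def test_unequal_variances(self):
        var, w_v, w_a, _ = fuse_1d(0.0, 0.0, 1.0, 3.0)
        assert w_v == pytest.approx(0.75)
        assert var == pytest.approx(0.75)
        assert w_v + w_a == pytest.approx(1.0)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            fuse_1d(0.0, 0.0, 0.0, 1.0)

    def test_estimate_maximizes_likelihood_product(self, rng):
        """Brute-force 1D grid argmax of the two-normal likelihood product."""
        for _ in range(10):
            r_v, r_a = rng.uniform(-3, 3, 2)
            var_v, var_a = rng.uniform(0.2, 4.0, 2)
            _, _, _, fused = fuse_1d(r_v, r_a, var_v, var_a)
            grid = np.linspace(min(r_v, r_a) - 1, max(r_v, r_a) + 1, 20_001)
            loglik = (-(grid - r_v) ** 2 / (2 * var_v)
                      - (grid - r_a) ** 2 / (2 * var_a))
            assert abs(grid[np.argmax(loglik)] - fused) <= np.diff(grid[:2])[0]


class TestFuse2D:
    def test_identical_isotropic_cues(self):
        d = DistributionSummary(0, 0, 1.0, 1.0, 0.0, n=0)
        f = fuse_gaussians_2d(d, d)
        assert np.allclose(f.cov, np.eye(2) / 2)
        assert np.allclose(f.mean, 0)
        assert f.w_visual_x == f.w_visual_y == 0.5

    def test_independent_axes_closed_form(self):
        v = DistributionSummary(1, 0, 1.0, 4.0, 0.0, n=0)
        a = DistributionSummary(0, 1, 4.0, 1.0, 0.0, n=0)
        f = fuse_gaussians_2d(v, a)
        assert np.allclose(f.mean, [0.8, 0.8])
        assert np.allclose(f.cov, np.diag([0.8, 0.8]))

    def test_dominant_cue_takes_all_weight(self):
        v = DistributionSummary(2, 3, 1e-8, 1e-8, 0.0, n=0)
        a = DistributionSummary(0, 0, 4.0, 4.0, 0.0, n=0)
        f = fuse_gaussians_2d(v, a)
        assert np.allclose(f.mean, [2, 3], atol=1e-6)
        assert f.w_visual_x > 1 - 1e-6

    def test_commutativity_with_swapped_weights(self, rng):
        v, a = _rand_pd_summary(rng), _rand_pd_summary(rng)
        f_va, f_av = fuse_gaussians_2d(v, a), fuse_gaussians_2d(a, v)
        assert np.allclose(f_va.mean, f_av.mean)
        assert np.allclose(f_va.cov, f_av.cov)
        assert f_va.w_visual_x == pytest.approx(f_av.w_auditory_x)

    def test_fused_spread_never_exceeds_either_cue(self, rng):
        for _ in range(30):
            v, a = _rand_pd_summary(rng), _rand_pd_summary(rng)
            f = fuse_gaussians_2d(v, a)
            assert np.linalg.det(f.cov) <= min(
                np.linalg.det(v.cov), np.linalg.det(a.cov)
            ) + 1e-12
            assert np.trace(f.cov) <= min(
                np.trace(v.cov), np.trace(a.cov)
            ) + 1e-12

    def test_diagonal_fused_mean_is_between_cues(self, rng):
        for _ in range(20):
            var_v, var_a = rng.uniform(0.2, 5.0, 2), rng.uniform(0.2, 5.0, 2)
            mu_v, mu_a = rng.uniform(-3, 3, 2), rng.uniform(-3, 3, 2)
            v = DistributionSummary(*mu_v, *var_v, 0.0, n=0)
            a = DistributionSummary(*mu_a, *var_a, 0.0, n=0)
            f = fuse_gaussians_2d(v, a)
            lo, hi = np.minimum(mu_v, mu_a), np.maximum(mu_v, mu_a)
            assert np.all(f.mean >= lo - 1e-12)
            assert np.all(f.mean <= hi + 1e-12)

    def test_singular_covariance_regularized_and_flagged(self):
        v = DistributionSummary(0, 0, 1.0, 0.0, 0.0, n=0, degenerate=True)
        a = DistributionSummary(0, 0, 1.0, 1.0, 0.0, n=0)
        f = fuse_gaussians_2d(v, a)
        assert f.regularized
        assert np.isfinite(f.cov).all()


class TestGridOracle:
    def test_matches_closed_form_on_random_pairs(self, rng):
        for _ in range(20):
            v, a = _rand_pd_summary(rng), _rand_pd_summary(rng)
            f = fuse_gaussians_2d(v, a)
            mean, cov = grid_product_oracle(v, a, grid_step=0.05)
            scale = np.sqrt(np.trace(f.cov))
            assert np.allclose(mean, f.mean, atol=1e-4 * scale)
            assert np.allclose(cov, f.cov, rtol=1e-4, atol=1e-4 * scale ** 2)

    def test_mirror_symmetric_inputs_fuse_onto_axis(self):
        v = DistributionSummary(1.0, 0.8, 1.0, 2.0, 0.3, n=0)
        a = DistributionSummary(1.0, -0.8, 1.0, 2.0, -0.3, n=0)
        mean, _ = grid_product_oracle(v, a, grid_step=0.05)
        assert mean[1] == pytest.approx(0.0, abs=1e-6)

    def test_step_halving_converges(self):
        v = DistributionSummary(0.5, -0.2, 1.0, 0.7, 0.2, n=0)
        a = DistributionSummary(-0.3, 0.4, 0.8, 1.5, -0.1, n=0)
        m1, c1 = grid_product_oracle(v, a, grid_step=0.04)
        m2, c2 = grid_product_oracle(v, a, grid_step=0.02)
        assert np.allclose(m1, m2, atol=1e-6)
        assert np.allclose(c1, c2, atol=1e-6)

    def test_narrow_grid_rejected(self):
        v = DistributionSummary(0, 0, 1.0, 1.0, 0.0, n=0)
        with pytest.raises(ValueError):
            grid_product_oracle(v, v, grid_halfwidth_sd=4.0)


class TestPredictedField:
    def test_matches_per_target_scalar_fusion(self):
        cfg = avloc.default_config(seed=0)
        v = avloc.ground_truth_field(cfg, "V")
        a = avloc.ground_truth_field(cfg, "A")
        field = predict_bimodal_field(v, a)
        t0 = v["target_id"].iloc[5]
        f = fuse_gaussians_2d(
            DistributionSummary(
                v.loc[5, "mu_x"], v.loc[5, "mu_y"], v.loc[5, "sigma_x2"],
                v.loc[5, "sigma_y2"], v.loc[5, "rho"], n=0,
            ),
            DistributionSummary(
                a.loc[5, "mu_x"], a.loc[5, "mu_y"], a.loc[5, "sigma_x2"],
                a.loc[5, "sigma_y2"], a.loc[5, "rho"], n=0,
            ),
        )
        row = field.set_index("target_id").loc[t0]
        assert row["sigma_x2"] == pytest.approx(f.cov[0, 0])
        assert row["mu_y"] == pytest.approx(f.mean[1])

    def test_total_variance_bound_per_target(self):
        cfg = avloc.default_config(seed=0)
        v = avloc.ground_truth_field(cfg, "V")
        a = avloc.ground_truth_field(cfg, "A")
        field = predict_bimodal_field(v, a)
        assert (
            field["sigma_xy2"]
            <= np.minimum(v["sigma_xy2"], a["sigma_xy2"]) + 1e-9
        ).all()

    def test_elevation_weight_exceeds_azimuth_weight(self):
        """Vision is relatively most reliable in elevation, so its Eq.-2
        weight is larger on the y axis than on the x axis."""
        cfg = avloc.default_config(seed=0)
        field = predict_bimodal_field(
            avloc.ground_truth_field(cfg, "V"), avloc.ground_truth_field(cfg, "A")
        )
        assert field["w_visual_y"].mean() > field["w_visual_x"].mean()

    def test_azimuth_weight_decreases_with_eccentricity(self):
        """Visual dispersion grows with |azimuth| while auditory does not,
        so the visual azimuth weight falls off toward the periphery."""
        cfg = avloc.default_config(seed=0)
        field = predict_bimodal_field(
            avloc.ground_truth_field(cfg, "V"), avloc.ground_truth_field(cfg, "A")
        ).merge(cfg.grid.to_frame(), on="target_id")
        hmp = field[field["el_deg"] == 0].copy()
        hmp["absaz"] = hmp["az_deg"].abs()
        w = hmp.groupby("absaz")["w_visual_x"].mean()
        assert (w.diff().dropna() < 0).all()

    def test_mismatched_targets_rejected(self):
        cfg = avloc.default_config(seed=0)
        v = avloc.ground_truth_field(cfg, "V")
        a = avloc.ground_truth_field(cfg, "A").iloc[:-1]
        with pytest.raises(ValueError):
            predict_bimodal_field(v, a)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_fusion_variance_inequality_random_pairs(seed):
    rng = np.random.default_rng(seed)
    var_v, var_a = rng.uniform(1e-3, 10.0, 2)
    var_f, w_v, w_a, _ = fuse_1d(0.0, 1.0, var_v, var_a)
    assert var_f <= min(var_v, var_a)
    assert w_v + w_a == pytest.approx(1.0)
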