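"""Maximum-likelihood fusion of visual and auditory location estimates.

For independent Gaussian cues with a flat prior over stimulus position, the
maximum-likelihood bimodal estimate is the reliability-weighted average of
the unimodal estimates:

    1D:   sigma_VA^2 = sigma_V^2 sigma_A^2 / (sigma_V^2 + sigma_A^2)
          W_V = (1/sigma_V^2) / (1/sigma_V^2 + 1/sigma_A^2),  W_A = 1 - W_V
          r_VA = W_V r_V + W_A r_A

    2D:   Sigma_VA = (Sigma_V^-1 + Sigma_A^-1)^-1
          mu_VA    = Sigma_VA (Sigma_V^-1 mu_V + Sigma_A^-1 mu_A)

The 2D rule is the precision-weighted product of the two bivariate normal
densities, i.e. the unique MLE when the corrupting noises are independent;
``grid_product_oracle`` verifies the algebra numerically by integrating the
pointwise density product on a grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dispersion import DistributionSummary

__all__ = [
    "FusionResult",
    "fuse_1d",
    "fuse_gaussians_2d",
    "fuse_covariances",
    "grid_product_oracle",
    "predict_bimodal_field",
]

#: relative jitter added to a singular covariance before inversion
_JITTER = 1e-8


@dataclass(frozen=True)
class FusionResult:
    """Predicted bimodal distribution and cue weights for one target."""

    mean: np.ndarray          # fused (mu_x, mu_y)
    cov: np.ndarray           # fused 2x2 covariance Sigma_VA
    w_visual_x: float         # per-axis Eq.-2 weights from marginal variances
    w_visual_y: float
    regularized: bool = False

    @property
    def w_auditory_x(self) -> float:
        return 1.0 - self.w_visual_x

    @property
    def w_auditory_y(self) -> float:
        return 1.0 - self.w_visual_y

    @property
    def w_visual_scalar(self) -> float:
        """Per-target scalar visual weight: mean of the two axis weights.

        Equals tr(Omega_V)/2 where Omega_V = Sigma_VA Sigma_V^-1 is the
        matrix weight on the visual estimate, for axis-aligned covariances.
        """
        return 0.5 * (self.w_visual_x + self.w_visual_y)

    @property
    def sigma_xy2(self) -> float:
        return float(self.cov[0, 0] + self.cov[1, 1])

    def to_summary(self) -> DistributionSummary:
        return DistributionSummary.from_moments(self.mean, self.cov, n=0)


def fuse_1d(r_v: float, r_a: float, var_v: float, var_a: float):
    """Scalar MLE fusion; returns (fused variance, W_V, W_A, fused estimate)."""
    if var_v <= 0 or var_a <= 0:
        raise ValueError("unimodal variances must be positive")
    var_va = var_v * var_a / (var_v + var_a)
    w_v = (1.0 / var_v) / (1.0 / var_v + 1.0 / var_a)
    w_a = 1.0 - w_v
    return var_va, w_v, w_a, w_v * r_v + w_a * r_a


def _inv2(m: np.ndarray) -> np.ndarray:
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    return np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det


def fuse_gaussians_2d(dist_v: DistributionSummary,
                      dist_a: DistributionSummary) -> FusionResult:
    """Full-covariance precision-weighted fusion of two bivariate normals.

    A singular covariance is regularized with a diagonal jitter of
    1e-8 x trace and flagged on the result.
    """
    cov_v, cov_a = dist_v.cov.copy(), dist_a.cov.copy()
    regularized = False
    for cov in (cov_v, cov_a):
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
        tr = cov[0, 0] + cov[1, 1]
        if tr <= 0:
            raise ValueError("covariance must be positive semi-definite and nonzero")
        if det <= _JITTER * tr ** 2:
            cov += np.eye(2) * _JITTER * tr
            regularized = True
    prec_v, prec_a = _inv2(cov_v), _inv2(cov_a)
    cov_va = _inv2(prec_v + prec_a)
    cov_va = 0.5 * (cov_va + cov_va.T)
    mean_va = cov_va @ (prec_v @ dist_v.mean + prec_a @ dist_a.mean)
    _, w_x, _, _ = fuse_1d(0.0, 0.0, cov_v[0, 0], cov_a[0, 0])
    _, w_y, _, _ = fuse_1d(0.0, 0.0, cov_v[1, 1], cov_a[1, 1])
    return FusionResult(mean_va, cov_va, w_x, w_y, regularized)


def fuse_covariances(mean_v: np.ndarray, cov_v: np.ndarray,
                     mean_a: np.ndarray, cov_a: np.ndarray):
    """Vectorised fusion of stacked (n, 2) means and (n, 2, 2) covariances."""
    def inv_stack(c):
        det = c[:, 0, 0] * c[:, 1, 1] - c[:, 0, 1] * c[:, 1, 0]
        out = np.empty_like(c)
        out[:, 0, 0] = c[:, 1, 1]
        out[:, 1, 1] = c[:, 0, 0]
        out[:, 0, 1] = -c[:, 0, 1]
        out[:, 1, 0] = -c[:, 1, 0]
        return out / det[:, None, None]

    prec = inv_stack(cov_v) + inv_stack(cov_a)
    cov_va = inv_stack(prec)
    rhs = np.einsum("nij,nj->ni", inv_stack(cov_v), mean_v) + np.einsum(
        "nij,nj->ni", inv_stack(cov_a), mean_a
    )
    mean_va = np.einsum("nij,nj->ni", cov_va, rhs)
    w_x = cov_a[:, 0, 0] / (cov_a[:, 0, 0] + cov_v[:, 0, 0])
    w_y = cov_a[:, 1, 1] / (cov_a[:, 1, 1] + cov_v[:, 1, 1])
    return mean_va, cov_va, w_x, w_y


def grid_product_oracle(dist_v: DistributionSummary,
                        dist_a: DistributionSummary,
                        grid_halfwidth_sd: float = 8.0,
                        grid_step: float = 0.05):
    """Numerical check of the fusion algebra, independent of it.

    Evaluates both bivariate normal densities on a regular grid, normalises
    their pointwise product, and returns its first two moments
    ``(mean (2,), covariance (2, 2))``.  The grid is centred on the two
    unimodal means and extends ``grid_halfwidth_sd`` marginal standard
    deviations beyond them; a grid narrower than 6 SD is rejected.
    """
    if grid_halfwidth_sd < 6.0:
        raise ValueError("grid must cover at least 6 SD of both densities")
    sds = np.sqrt([
        dist_v.sigma_x2, dist_a.sigma_x2, dist_v.sigma_y2, dist_a.sigma_y2,
    ])
    span_x = grid_halfwidth_sd * max(sds[0], sds[1])
    span_y = grid_halfwidth_sd * max(sds[2], sds[3])
    lo_x = min(dist_v.mu_x, dist_a.mu_x) - span_x
    hi_x = max(dist_v.mu_x, dist_a.mu_x) + span_x
    lo_y = min(dist_v.mu_y, dist_a.mu_y) - span_y
    hi_y = max(dist_v.mu_y, dist_a.mu_y) + span_y
    xs = np.arange(lo_x, hi_x + grid_step, grid_step)
    ys = np.arange(lo_y, hi_y + grid_step, grid_step)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)

    def logpdf(d: DistributionSummary) -> np.ndarray:
        diff = pts - d.mean
        prec = _inv2(d.cov)
        return -0.5 * np.einsum("ni,ij,nj->n", diff, prec, diff)

    logw = logpdf(dist_v) + logpdf(dist_a)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    mean = w @ pts
    diff = pts - mean
    cov = (w[:, None] * diff).T @ diff
    return mean, cov


def predict_bimodal_field(summaries_v: pd.DataFrame,
                          summaries_a: pd.DataFrame,
                          by: list[str] | None = None) -> pd.DataFrame:
    """Per-target MLE prediction of the bimodal field (the 'MLE condition').

    Both inputs are tables from ``estimate_distribution_table`` keyed by the
    same grouping columns (default ``['target_id']``; include 'subject' for
    subject-level prediction).  Returns a table with the same moment columns
    so downstream stages (ellipses, error vectors) treat the prediction
    exactly like an observed modality, plus the per-axis visual weights.
    """
    by = by or ["target_id"]
    cols = ["mu_x", "mu_y", "sigma_x2", "sigma_y2", "cov_xy"]
    v = summaries_v.set_index(by)[cols + ["n"]]
    a = summaries_a.set_index(by)[cols + ["n"]]
    if not v.index.equals(a.index):
        if set(v.index) != set(a.index):
            raise ValueError("visual and auditory fields cover different targets")
        a = a.reindex(v.index)

    def stack(tab):
        mean = tab[["mu_x", "mu_y"]].to_numpy(dtype=float)
        cov = np.empty((len(tab), 2, 2))
        cov[:, 0, 0] = tab["sigma_x2"]
        cov[:, 1, 1] = tab["sigma_y2"]
        cov[:, 0, 1] = cov[:, 1, 0] = tab["cov_xy"]
        return mean, cov

    mean_v, cov_v = stack(v)
    mean_a, cov_a = stack(a)
    mean_va, cov_va, w_x, w_y = fuse_covariances(mean_v, cov_v, mean_a, cov_a)
    out = pd.DataFrame(index=v.index).reset_index()
    out["n"] = np.minimum(v["n"].to_numpy(), a["n"].to_numpy())
    out["mu_x"], out["mu_y"] = mean_va[:, 0], mean_va[:, 1]
    out["sigma_x2"], out["sigma_y2"] = cov_va[:, 0, 0], cov_va[:, 1, 1]
    out["cov_xy"] = cov_va[:, 0, 1]
    denom = np.sqrt(out["sigma_x2"] * out["sigma_y2"])
    out["rho"] = np.where(denom > 0, out["cov_xy"] / denom, 0.0)
    out["degenerate"] = False
    out["sigma_xy2"] = out["sigma_x2"] + out["sigma_y2"]
    out["w_visual_x"], out["w_visual_y"] = w_x, w_y
    out["w_visual"] = 0.5 * (w_x + w_y)
    return out
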