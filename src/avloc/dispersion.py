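"""Per-target bivariate response statistics and confidence-ellipse geometry.

The precision stage: repeated pointing responses to one target are treated
as draws from a bivariate normal.  Each cell is summarised by its centroid
(mu_x, mu_y), per-axis variances, correlation and the 2D variance
sigma_xy^2 = sigma_x^2 + sigma_y^2; dispersion is visualised and analysed
through the coverage ellipse of that normal:

    semi-axes  a, b = sqrt(lambda_i * q),   q = chi2_2^{-1}(coverage)

with lambda_i the covariance eigenvalues.  The ellipse orientation theta_a
is the axial (0-180 deg) angle of the leading eigenvector, and the
anisotropy ratio eps = b/a runs from 0 (a preferred direction) to 1 (none).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DistributionSummary",
    "Ellipse",
    "estimate_distribution",
    "estimate_distribution_table",
    "confidence_ellipse",
    "ellipse_table",
    "axial_deviation",
    "anisotropy_printed",
]

#: variance below which an axis is considered collapsed (degrees^2)
_DEGENERATE_VAR = 1e-12


@dataclass(frozen=True)
class DistributionSummary:
    """Bivariate moments of one response cell (or one population).

    ``n`` is the sample size; ``n = 0`` marks an exact population summary
    (e.g. a generator ground truth).  ``sigma_xy2`` is kept equal to
    ``sigma_x2 + sigma_y2`` by construction.
    """

    mu_x: float
    mu_y: float
    sigma_x2: float
    sigma_y2: float
    rho: float
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sigma_x2 < 0 or self.sigma_y2 < 0:
            raise ValueError("variances must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")

    @property
    def sigma_xy2(self) -> float:
        """Total 2D variance (sum of the two orthogonal variances)."""
        return self.sigma_x2 + self.sigma_y2

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mu_x, self.mu_y])

    @property
    def cov(self) -> np.ndarray:
        c = self.rho * np.sqrt(self.sigma_x2 * self.sigma_y2)
        return np.array([[self.sigma_x2, c], [c, self.sigma_y2]])

    @classmethod
    def from_moments(cls, mean: np.ndarray, cov: np.ndarray,
                     n: int = 0) -> "DistributionSummary":
        vx, vy = float(cov[0, 0]), float(cov[1, 1])
        degenerate = vx <= _DEGENERATE_VAR or vy <= _DEGENERATE_VAR
        rho = 0.0 if degenerate else float(cov[0, 1] / np.sqrt(vx * vy))
        rho = float(np.clip(rho, -1.0, 1.0))
        return cls(float(mean[0]), float(mean[1]), vx, vy, rho, n, degenerate)


@dataclass(frozen=True)
class Ellipse:
    """Coverage-ellipse geometry of a bivariate normal."""

    a: float            # major semi-axis, degrees
    b: float            # minor semi-axis, degrees
    theta_deg: float    # axial orientation of the major eigenvector, [0, 180)
    coverage: float
    orientation_defined: bool = True

    def __post_init__(self) -> None:
        if self.b > self.a + 1e-9:
            raise ValueError("major semi-axis must be >= minor semi-axis")

    @property
    def anisotropy(self) -> float:
        """Ellipse ratio eps = b/a in [0, 1]; 1 means no preferred direction."""
        return self.b / self.a if self.a > 0 else 0.0


def anisotropy_printed(ellipse: Ellipse) -> float:
    """Alternative anisotropy index 1 - (b/a)^2.

    Provided for completeness; inconsistent with the reading 'close to 1
    indicating no preferred direction' and with every value the b/a ratio
    convention reproduces, so not used by the pipeline.
    """
    return 1.0 - ellipse.anisotropy ** 2


def estimate_distribution(points: np.ndarray) -> DistributionSummary:
    """Unbiased (n-1) sample moments of a set of (x, y) responses."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 2:
        raise ValueError("at least two points are required")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    return DistributionSummary.from_moments(mean, cov, n=n)


def estimate_distribution_table(frame: pd.DataFrame,
                                by: list[str]) -> pd.DataFrame:
    """Vectorised per-cell moments for a trial table.

    ``frame`` needs columns x_deg, y_deg; returns one row per group with
    columns n, mu_x, mu_y, sigma_x2, sigma_y2, cov_xy, rho, sigma_xy2 and a
    degenerate flag.  Cells with fewer than two responses are dropped.
    """
    work = frame[by].copy()
    work["x"] = frame["x_deg"].to_numpy(dtype=float)
    work["y"] = frame["y_deg"].to_numpy(dtype=float)
    work["xy"] = work["x"] * work["y"]
    g = work.groupby(by, sort=True, observed=True)
    out = g.agg(
        n=("x", "size"),
        mu_x=("x", "mean"),
        mu_y=("y", "mean"),
        sigma_x2=("x", "var"),
        sigma_y2=("y", "var"),
        m_xy=("xy", "mean"),
    ).reset_index()
    out = out[out["n"] >= 2].copy()
    n = out["n"].to_numpy(dtype=float)
    out["cov_xy"] = (out["m_xy"] - out["mu_x"] * out["mu_y"]) * n / (n - 1.0)
    out["degenerate"] = (out["sigma_x2"] <= _DEGENERATE_VAR) | (
        out["sigma_y2"] <= _DEGENERATE_VAR
    )
    denom = np.sqrt(out["sigma_x2"] * out["sigma_y2"])
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(out["degenerate"], 0.0, out["cov_xy"] / denom)
    out["rho"] = np.clip(rho, -1.0, 1.0)
    out["sigma_xy2"] = out["sigma_x2"] + out["sigma_y2"]
    return out.drop(columns="m_xy")


def _eigen2x2(vx: np.ndarray, vy: np.ndarray, cxy: np.ndarray):
    """Closed-form eigenstructure of symmetric 2x2 covariance arrays."""
    half_tr = (vx + vy) / 2.0
    half_diff = (vx - vy) / 2.0
    disc = np.sqrt(half_diff ** 2 + cxy ** 2)
    lam1 = half_tr + disc
    lam2 = np.clip(half_tr - disc, 0.0, None)
    theta = np.degrees(0.5 * np.arctan2(2.0 * cxy, vx - vy)) % 180.0
    return lam1, lam2, theta, disc


def confidence_ellipse(summary: DistributionSummary,
                       coverage: float = 0.95) -> Ellipse:
    """Coverage ellipse of a cell's fitted bivariate normal.

    Isotropic covariances have no preferred direction: the orientation is
    reported as 0 with ``orientation_defined=False``.  A degenerate
    (collapsed-axis) covariance yields b = 0 with the orientation along the
    surviving data axis.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    q = stats.chi2.ppf(coverage, df=2)
    cov = summary.cov
    lam1, lam2, theta, disc = _eigen2x2(
        np.asarray(cov[0, 0]), np.asarray(cov[1, 1]), np.asarray(cov[0, 1])
    )
    lam1, lam2, theta, disc = float(lam1), float(lam2), float(theta), float(disc)
    defined = disc > 1e-12 * max(lam1, 1e-300)
    return Ellipse(
        a=float(np.sqrt(lam1 * q)),
        b=float(np.sqrt(lam2 * q)),
        theta_deg=theta if defined else 0.0,
        coverage=coverage,
        orientation_defined=defined,
    )


def ellipse_table(summaries: pd.DataFrame, coverage: float = 0.95) -> pd.DataFrame:
    """Vectorised ellipse geometry for a table from estimate_distribution_table.

    Adds columns a, b, theta_deg, anisotropy, orientation_defined.
    """
    q = stats.chi2.ppf(coverage, df=2)
    vx = summaries["sigma_x2"].to_numpy(dtype=float)
    vy = summaries["sigma_y2"].to_numpy(dtype=float)
    cxy = summaries["cov_xy"].to_numpy(dtype=float)
    lam1, lam2, theta, disc = _eigen2x2(vx, vy, cxy)
    out = summaries.copy()
    defined = disc > 1e-12 * np.maximum(lam1, 1e-300)
    out["a"] = np.sqrt(lam1 * q)
    out["b"] = np.sqrt(lam2 * q)
    out["theta_deg"] = np.where(defined, theta, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["anisotropy"] = np.where(lam1 > 0, np.sqrt(lam2 / lam1), 0.0)
    out["orientation_defined"] = defined
    return out


def axial_deviation(theta_deg, direction_deg):
    """Axial distance between an orientation and a target direction, [0, 90].

    Both angles are reduced modulo 180 (an axis has no arrowhead) and the
    difference is folded so that 170 vs 10 gives 20, not 160.  Accepts
    scalars or arrays.
    """
    delta = np.abs(np.asarray(theta_deg, dtype=float)
                   - np.asarray(direction_deg, dtype=float)) % 180.0
    out = np.minimum(delta, 180.0 - delta)
    return float(out) if out.ndim == 0 else out
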