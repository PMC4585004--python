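"""Constant-error vectors, distortion grids, and the global affine map.

The accuracy stage treats each per-target response centroid as the image
of its target under the (unknown) internal target-to-endpoint mapping.
Local structure is summarised by the error vector (centroid - target) in
amplitude/direction form; global structure by the best least-squares
affine map and by the 4-neighbour distortion grid, whose edge-length
ratios and orientation flips show how faithfully the spatial layout of
the targets survives into the response layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dispersion import DistributionSummary
from .grid import Target, TargetGrid

__all__ = [
    "ErrorVector",
    "AffineMap",
    "DistortionGrid",
    "error_vector",
    "error_vector_table",
    "fit_affine",
    "distortion_grid",
]


@dataclass(frozen=True)
class ErrorVector:
    """Constant error of one target: centroid minus target position."""

    dx: float
    dy: float
    target_direction_deg: float | None   # None for the central target

    @property
    def r(self) -> float:
        """Amplitude (the constant error), degrees."""
        return float(np.hypot(self.dx, self.dy))

    @property
    def alpha_deg(self) -> float | None:
        """Vector direction in [0, 360); undefined (None) when r = 0."""
        if self.r == 0.0:
            return None
        return float(np.degrees(np.arctan2(self.dy, self.dx)) % 360.0)

    @property
    def circular_deviation_deg(self) -> float | None:
        """Circular distance between alpha and the target direction, [0, 180].

        180 means the error points straight back toward fixation (pure
        undershoot).  None when either direction is undefined.
        """
        if self.alpha_deg is None or self.target_direction_deg is None:
            return None
        delta = abs(self.alpha_deg - self.target_direction_deg) % 360.0
        return min(delta, 360.0 - delta)

    @property
    def axial_deviation_deg(self) -> float | None:
        """Circular deviation folded at 180 into [0, 90] (axis convention)."""
        c = self.circular_deviation_deg
        if c is None:
            return None
        c = c if c <= 180.0 else 360.0 - c
        return min(c, 180.0 - c)


def error_vector(summary: DistributionSummary, target: Target) -> ErrorVector:
    """Error vector of a cell summary relative to its target."""
    direction = None
    if not (target.azimuth == 0.0 and target.elevation == 0.0):
        direction = target.direction_deg
    return ErrorVector(
        dx=summary.mu_x - target.azimuth,
        dy=summary.mu_y - target.elevation,
        target_direction_deg=direction,
    )


def error_vector_table(summaries: pd.DataFrame, grid: TargetGrid) -> pd.DataFrame:
    """Vectorised error vectors for a per-target summary table.

    Adds columns r, alpha_deg, circular_dev_deg, axial_dev_deg (the last
    three NaN where undefined: zero-amplitude vectors or the central
    target).
    """
    gt = grid.to_frame()
    out = summaries.merge(gt, on="target_id", how="left")
    dx = out["mu_x"].to_numpy() - out["az_deg"].to_numpy()
    dy = out["mu_y"].to_numpy() - out["el_deg"].to_numpy()
    r = np.hypot(dx, dy)
    alpha = np.degrees(np.arctan2(dy, dx)) % 360.0
    central = (out["az_deg"] == 0) & (out["el_deg"] == 0)
    tdir = np.degrees(np.arctan2(out["el_deg"], out["az_deg"])) % 360.0
    delta = np.abs(alpha - tdir) % 360.0
    circ = np.minimum(delta, 360.0 - delta)
    axial = np.minimum(circ, 180.0 - circ)
    undef = central.to_numpy() | (r == 0)
    out["r"] = r
    out["alpha_deg"] = np.where(r == 0, np.nan, alpha)
    out["circular_dev_deg"] = np.where(undef, np.nan, circ)
    out["axial_dev_deg"] = np.where(undef, np.nan, np.abs(axial))
    return out


@dataclass(frozen=True)
class AffineMap:
    """Least-squares affine target-to-endpoint map and its decomposition.

    The linear part factors as rotation o shear o scale:

        L = R(theta) @ [[1, k], [0, 1]] @ diag(sx, sy)

    obtained from the QR factorization of L with positive diagonal; a
    reflection, if present, is carried by a negative sy.
    """

    linear: np.ndarray        # 2x2
    translation: np.ndarray   # (2,)
    rms_residual: float

    @property
    def _qr(self):
        q, r = np.linalg.qr(self.linear)
        signs = np.sign(np.diag(r))
        signs[signs == 0] = 1.0
        q = q * signs
        r = signs[:, None] * r
        if np.linalg.det(q) < 0:   # push the reflection into sy
            q = q @ np.diag([1.0, -1.0])
            r = np.diag([1.0, -1.0]) @ r
        return q, r

    @property
    def rotation_deg(self) -> float:
        q, _ = self._qr
        return float(np.degrees(np.arctan2(q[1, 0], q[0, 0])))

    @property
    def scale_x(self) -> float:
        return float(self._qr[1][0, 0])

    @property
    def scale_y(self) -> float:
        return float(self._qr[1][1, 1])

    @property
    def shear(self) -> float:
        _, r = self._qr
        return float(r[0, 1] / r[1, 1])

    def recompose(self) -> np.ndarray:
        q, _ = self._qr
        return q @ np.array([[1.0, self.shear], [0.0, 1.0]]) @ np.diag(
            [self.scale_x, self.scale_y]
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.linear.T + self.translation


def fit_affine(targets: np.ndarray, centroids: np.ndarray) -> AffineMap:
    """Least-squares affine fit of centroids = L @ targets + t.

    Needs at least three non-collinear targets; collinear layouts raise.
    """
    t = np.asarray(targets, dtype=float)
    c = np.asarray(centroids, dtype=float)
    if t.shape != c.shape or t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("targets and centroids must be matching (n, 2) arrays")
    if t.shape[0] < 3:
        raise ValueError("at least 3 target/centroid pairs are required")
    design = np.column_stack([t, np.ones(len(t))])
    if np.linalg.matrix_rank(design) < 3:
        raise np.linalg.LinAlgError("targets are collinear; affine fit is rank-deficient")
    coef, _, _, _ = np.linalg.lstsq(design, c, rcond=None)
    linear = coef[:2].T
    translation = coef[2]
    resid = c - (t @ linear.T + translation)
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return AffineMap(linear=linear, translation=translation, rms_residual=rms)


@dataclass(frozen=True)
class DistortionGrid:
    """4-neighbour edge map between target layout and response centroids."""

    edges: pd.DataFrame        # id_a, id_b, target_length, response_length, length_ratio
    fold_over: bool            # any grid cell flipped orientation
    flipped_cells: tuple[tuple[int, int, int, int], ...]
    missing_edges: tuple[tuple[int, int], ...]


def _signed_area(p0, p1, p2) -> float:
    return 0.5 * float(
        (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (p1[1] - p0[1])
    )


def distortion_grid(centroids: dict[int, np.ndarray],
                    grid: TargetGrid) -> DistortionGrid:
    """Link centroids of 4-neighbour adjacent targets.

    Per-edge the ratio response-length / target-length is reported; a cell
    whose mapped quadrilateral changes orientation (either triangle of the
    quad flips sign against the target layout) raises the fold-over flag.
    Targets without a centroid are skipped and their edges reported missing.
    """
    pos = {t.id: (t.azimuth, t.elevation) for t in grid}
    step = grid.spacing_deg
    index = {(t.azimuth, t.elevation): t.id for t in grid}

    edges, missing = [], []
    for t in grid:
        for dx, dy in ((step, 0.0), (0.0, step)):
            key = (t.azimuth + dx, t.elevation + dy)
            if key not in index:
                continue
            other = index[key]
            if t.id not in centroids or other not in centroids:
                missing.append((t.id, other))
                continue
            tlen = float(np.hypot(dx, dy))
            rlen = float(np.linalg.norm(
                np.asarray(centroids[other]) - np.asarray(centroids[t.id])
            ))
            edges.append((t.id, other, tlen, rlen, rlen / tlen))
    edge_frame = pd.DataFrame(
        edges, columns=["id_a", "id_b", "target_length", "response_length",
                        "length_ratio"],
    )

    flipped = []
    for t in grid:
        quad_keys = [
            (t.azimuth, t.elevation),
            (t.azimuth + step, t.elevation),
            (t.azimuth + step, t.elevation + step),
            (t.azimuth, t.elevation + step),
        ]
        if not all(k in index for k in quad_keys):
            continue
        ids = [index[k] for k in quad_keys]
        if not all(i in centroids for i in ids):
            continue
        tq = [np.asarray(pos[i]) for i in ids]
        rq = [np.asarray(centroids[i]) for i in ids]
        for tri in ((0, 1, 2), (0, 2, 3)):
            ta = _signed_area(*(tq[i] for i in tri))
            ra = _signed_area(*(rq[i] for i in tri))
            if ta != 0 and np.sign(ra) != np.sign(ta):
                flipped.append(tuple(ids))
                break
    return DistortionGrid(
        edges=edge_frame,
        fold_over=bool(flipped),
        flipped_cells=tuple(flipped),
        missing_edges=tuple(missing),
    )
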