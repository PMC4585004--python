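"""Trial-level localization records: IO, the outlier rule, and groupings.

A dataset is a flat table of pointing endpoints, one row per
subject x modality x target x repetition, with the target grid attached as
metadata.  On disk it is a comma-delimited file with header

    subject,modality,target_id,rep,x_deg,y_deg

plus a grid sidecar ``<stem>.grid.csv`` with ``target_id,az_deg,el_deg``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import TargetGrid

__all__ = [
    "MODALITIES",
    "ResponseDataset",
    "RemovalReport",
    "read_responses",
    "write_responses",
    "filter_outliers",
    "select_subset",
]

MODALITIES = ("A", "V", "VA")
COLUMNS = ["subject", "modality", "target_id", "rep", "x_deg", "y_deg"]


@dataclass(frozen=True)
class ResponseDataset:
    """Trial records plus the grid they refer to."""

    frame: pd.DataFrame
    grid: TargetGrid

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        if len(self.frame):
            if not np.isfinite(self.frame[["x_deg", "y_deg"]].to_numpy()).all():
                raise ValueError("response coordinates must be finite")
            bad = set(self.frame["modality"].unique()) - set(MODALITIES)
            if bad:
                raise ValueError(f"unknown modality values: {sorted(bad)}")
            known = set(self.grid.ids.tolist())
            orphan = set(self.frame["target_id"].unique()) - known
            if orphan:
                raise ValueError(f"records reference unknown targets: {sorted(orphan)}")
            keys = self.frame[["subject", "modality", "target_id", "rep"]]
            if keys.duplicated().any():
                raise ValueError("(subject, modality, target, rep) must be unique")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def modalities(self) -> list[str]:
        return sorted(self.frame["modality"].unique())

    def with_frame(self, frame: pd.DataFrame) -> "ResponseDataset":
        return ResponseDataset(frame.reset_index(drop=True), self.grid)

    def with_targets(self) -> pd.DataFrame:
        """Records joined with target coordinates (columns az_deg, el_deg)."""
        return self.frame.merge(self.grid.to_frame(), on="target_id", how="left")


@dataclass(frozen=True)
class RemovalReport:
    """Accounting of the +/-k SD outlier pass."""

    per_cell: pd.DataFrame        # subject, modality, target_id, n_before, n_removed, small_cell
    k: float

    @property
    def per_modality(self) -> pd.Series:
        g = self.per_cell.groupby("modality")
        return g["n_removed"].sum() / g["n_before"].sum()

    @property
    def n_removed(self) -> int:
        return int(self.per_cell["n_removed"].sum())

    @property
    def small_cells(self) -> pd.DataFrame:
        return self.per_cell[self.per_cell["small_cell"]]


def _grid_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".grid.csv") if path.suffix else path


def write_responses(dataset: ResponseDataset, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.frame[COLUMNS].to_csv(path, index=False, float_format="%.6f")
    dataset.grid.to_frame().to_csv(
        path.with_suffix(".grid.csv"), index=False, float_format="%.6f"
    )


def read_responses(path: str | Path,
                   grid: TargetGrid | None = None) -> ResponseDataset:
    """Read a trial table; the grid comes from the sidecar unless given.

    Malformed rows are reported with their line numbers; a file holding
    only the header yields an empty dataset.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"subject": str, "modality": str})
    missing = set(COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(
            f"{path.name}: missing required column(s) {sorted(missing)}"
        )
    for col in ("x_deg", "y_deg"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header and 0-base
            raise ValueError(f"{path.name}: non-numeric {col} at line(s) {lines}")
        frame[col] = coerced
    if frame[["x_deg", "y_deg"]].isna().any(axis=None):
        bad = frame.index[frame[["x_deg", "y_deg"]].isna().any(axis=1)]
        lines = [int(i) + 2 for i in bad[:5]]
        raise ValueError(f"{path.name}: missing coordinates at line(s) {lines}")
    if grid is None:
        sidecar = path.with_suffix(".grid.csv")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no grid given and sidecar {sidecar.name} not found"
            )
        grid = TargetGrid.from_frame(pd.read_csv(sidecar))
    frame["target_id"] = frame["target_id"].astype(int)
    frame["rep"] = frame["rep"].astype(int)
    return ResponseDataset(frame.reset_index(drop=True), grid)


def filter_outliers(dataset: ResponseDataset,
                    k: float = 3.0) -> tuple[ResponseDataset, RemovalReport]:
    """Remove responses beyond k sample SD of their cell mean, per axis.

    The rule is applied in a single pass within each
    (subject, modality, target) cell, with the mean and SD taken from the
    unfiltered cell; a record is removed if it exceeds the bound on the x
    OR the y axis.  Cells with fewer than 3 repetitions are passed through
    untouched and flagged in the report.

    Note the hard bound max |x - mean| / sd = (n-1)/sqrt(n) for a sample of
    size n: with 10 repetitions per cell no single response can exceed 2.85
    sample SDs, so at that cell size the rule is structurally unable to
    remove anything; it only bites for larger cells.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    frame = dataset.frame
    if not len(frame):
        report = RemovalReport(
            pd.DataFrame(columns=["subject", "modality", "target_id",
                                  "n_before", "n_removed", "small_cell"]),
            k,
        )
        return dataset, report
    by = ["subject", "modality", "target_id"]
    g = frame.groupby(by, sort=False)
    n = g["x_deg"].transform("size")
    small = n < 3
    keep = pd.Series(True, index=frame.index)
    for col in ("x_deg", "y_deg"):
        mean = g[col].transform("mean")
        sd = g[col].transform("std")
        keep &= (frame[col] - mean).abs() <= k * sd.fillna(np.inf)
    keep |= small
    removed = frame.loc[~keep, by].assign(removed=1)
    cells = frame[by].assign(n_before=1)
    per_cell = cells.groupby(by, sort=True).size().rename("n_before").reset_index()
    rem_counts = (
        removed.groupby(by, sort=True).size().rename("n_removed").reset_index()
        if len(removed)
        else pd.DataFrame(columns=by + ["n_removed"])
    )
    per_cell = per_cell.merge(rem_counts, on=by, how="left")
    per_cell["n_removed"] = (
        pd.to_numeric(per_cell["n_removed"], errors="coerce").fillna(0).astype(int)
    )
    per_cell["small_cell"] = per_cell["n_before"] < 3
    return dataset.with_frame(frame[keep]), RemovalReport(per_cell, k)


def select_subset(dataset: ResponseDataset,
                  modality: str | None = None,
                  hemifield: str | None = None,
                  axis: str | None = None,
                  max_eccentricity: float | None = None,
                  max_abs_azimuth: float | None = None) -> ResponseDataset:
    """Select records by modality and target geometry.

    hemifield: 'upper' (el > 0), 'lower' (el < 0), 'HMP' (el = 0),
    'SMP' (az = 0).  axis: 'X' (el = 0), 'Y' (az = 0),
    'XY' (|az| = |el| != 0, the oblique diagonals).  ``max_abs_azimuth=20``
    reproduces the 25-target analysis grid that drops the +/-30 deg
    azimuth columns.  An empty selection is allowed (the caller is expected
    to check ``len``); grid metadata is preserved, restricted to the kept
    geometry.
    """
    def geom_mask(az, el):
        mask = np.ones(np.shape(az), dtype=bool)
        if hemifield is not None:
            rules = {
                "upper": el > 0, "lower": el < 0, "HMP": el == 0, "SMP": az == 0,
            }
            if hemifield not in rules:
                raise ValueError(f"unknown hemifield {hemifield!r}")
            mask &= rules[hemifield]
        if axis is not None:
            rules = {
                "X": el == 0,
                "Y": az == 0,
                "XY": (np.abs(az) == np.abs(el)) & (az != 0),
            }
            if axis not in rules:
                raise ValueError(f"unknown axis {axis!r}")
            mask &= rules[axis]
        if max_eccentricity is not None:
            mask &= np.hypot(az, el) <= max_eccentricity
        if max_abs_azimuth is not None:
            mask &= np.abs(az) <= max_abs_azimuth
        return mask

    if modality is not None and modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    pos = dataset.grid.positions
    grid_keep = geom_mask(pos[:, 0], pos[:, 1])
    grid = TargetGrid(
        targets=tuple(t for t, k in zip(dataset.grid, grid_keep) if k),
        spacing_deg=dataset.grid.spacing_deg,
    )
    frame = dataset.with_targets()
    mask = geom_mask(frame["az_deg"].to_numpy(), frame["el_deg"].to_numpy())
    if modality is not None:
        mask &= (frame["modality"] == modality).to_numpy()
    kept = frame.loc[mask, COLUMNS].reset_index(drop=True)
    if not len(kept):
        warnings.warn("select_subset produced an empty selection", stacklevel=2)
    return ResponseDataset(kept, grid)
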