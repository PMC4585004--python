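"""Target grids for 2D frontal-field localization experiments.

Coordinates are planar degrees: azimuth positive rightward, elevation
positive upward, fixation at the origin.  The canonical stimulus layout is
a 7 x 5 matrix of loudspeaker/light-spot positions at 10 deg spacing,
spanning +/-30 deg azimuth and +/-20 deg elevation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["Target", "TargetGrid", "build_target_grid"]


@dataclass(frozen=True)
class Target:
    """One stimulus location, in degrees azimuth/elevation."""

    id: int
    azimuth: float
    elevation: float

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.azimuth, self.elevation))

    @property
    def direction_deg(self) -> float:
        """Direction from fixation, degrees CCW from rightward, in [0, 360)."""
        if self.azimuth == 0.0 and self.elevation == 0.0:
            raise ValueError("direction undefined for the central target")
        return float(np.degrees(np.arctan2(self.elevation, self.azimuth)) % 360.0)


@dataclass(frozen=True)
class TargetGrid:
    """An immutable collection of targets with unique integer ids."""

    targets: tuple[Target, ...]
    spacing_deg: float = 10.0

    def __post_init__(self) -> None:
        ids = [t.id for t in self.targets]
        if len(set(ids)) != len(ids):
            raise ValueError("target ids must be unique")

    def __len__(self) -> int:
        return len(self.targets)

    def __iter__(self) -> Iterator[Target]:
        return iter(self.targets)

    def __getitem__(self, target_id: int) -> Target:
        try:
            return self._by_id[target_id]
        except KeyError:
            raise KeyError(f"unknown target id {target_id!r}") from None

    @property
    def _by_id(self) -> dict[int, Target]:
        return {t.id: t for t in self.targets}

    @property
    def ids(self) -> np.ndarray:
        return np.array([t.id for t in self.targets])

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (azimuth, elevation)."""
        return np.array([[t.azimuth, t.elevation] for t in self.targets], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target_id": self.ids,
                "az_deg": self.positions[:, 0],
                "el_deg": self.positions[:, 1],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, spacing_deg: float = 10.0) -> "TargetGrid":
        required = {"target_id", "az_deg", "el_deg"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"grid table missing columns: {sorted(missing)}")
        targets = tuple(
            Target(int(r.target_id), float(r.az_deg), float(r.el_deg))
            for r in frame.itertuples()
        )
        return cls(targets=targets, spacing_deg=spacing_deg)

    def subset(self, max_abs_azimuth: float | None = None,
               max_abs_elevation: float | None = None) -> "TargetGrid":
        """Restrict the grid, e.g. drop the +/-30 deg azimuth columns."""
        kept = []
        for t in self.targets:
            if max_abs_azimuth is not None and abs(t.azimuth) > max_abs_azimuth:
                continue
            if max_abs_elevation is not None and abs(t.elevation) > max_abs_elevation:
                continue
            kept.append(t)
        return TargetGrid(targets=tuple(kept), spacing_deg=self.spacing_deg)


def build_target_grid(n_az: int = 7, n_el: int = 5,
                      spacing_deg: float = 10.0) -> TargetGrid:
    """Build a centred, symmetric n_az x n_el grid with row-major ids.

    Both counts must be odd so the grid contains the central (0, 0) target.
    Rows run over elevation (bottom to top), columns over azimuth (left to
    right); ids are row-major starting at 0.
    """
    if n_az < 1 or n_el < 1:
        raise ValueError("grid counts must be >= 1")
    if n_az % 2 == 0 or n_el % 2 == 0:
        raise ValueError("grid counts must be odd so the grid has a centre target")
    if spacing_deg <= 0:
        raise ValueError("spacing must be positive")
    azimuths = (np.arange(n_az) - n_az // 2) * spacing_deg
    elevations = (np.arange(n_el) - n_el // 2) * spacing_deg
    targets = []
    tid = 0
    for el in elevations:
        for az in azimuths:
            targets.append(Target(tid, float(az), float(el)))
            tid += 1
    return TargetGrid(targets=tuple(targets), spacing_deg=float(spacing_deg))
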