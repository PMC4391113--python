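"""Geometry of the Humphrey 30-2 stimulus grid.

The 30-2 pattern tests 76 locations on a 6-degree lattice offset 3 degrees
from the horizontal and vertical meridians, covering the central 30 degrees
of the visual field.  All analysis in this package is carried out in
right-eye visual-field space: x > 0 is the temporal field, y > 0 the
superior field, and the physiological blind spot sits at (15, +/-3).  The
two locations immediately above and below the blind spot are excluded from
analysis, leaving 74 analysable locations.

The analysable field is sectorised into three concentric zones of
eccentricity: an inner zone of 30 points (4.2-17.5 deg from fixation), a
middle zone of 20 points (21.2-22.8 deg) and an outer zone of 24 points
(25.8-28.5 deg).  Zone bounds are compared on eccentricity rounded to one
decimal place; the rounding convention is the single source of truth for
zone membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Zone",
    "StimulusLocation",
    "StimulusGrid",
    "build_grid_30_2",
    "assign_zone",
    "BLIND_SPOT_ADJACENT",
    "GRID_30_2",
]

#: Half-coordinates of the 30-2 lattice (degrees).
_LATTICE = (-27, -21, -15, -9, -3, 3, 9, 15, 21, 27)

#: Outer radius of the 30-2 pattern (degrees); (27, 9) at 28.46 deg is the
#: most eccentric tested location.
_MAX_ECCENTRICITY = 28.5

#: Locations immediately above and below the blind spot of a right eye.
BLIND_SPOT_ADJACENT = frozenset({(15, 3), (15, -3)})

# Zone bounds in degrees, applied to eccentricity rounded to 1 dp.
_ZONE_BOUNDS = {
    "inner": (4.2, 17.5),
    "middle": (21.2, 22.8),
    "outer": (25.8, 28.5),
}


class Zone(str, Enum):
    """Eccentricity sector of a stimulus location."""

    INNER = "inner"
    MIDDLE = "middle"
    OUTER = "outer"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class StimulusLocation:
    """One test point of the grid, in right-eye visual-field degrees."""

    x: float
    y: float
    eccentricity: float
    zone: Zone

    @property
    def analysable(self) -> bool:
        return self.zone is not Zone.EXCLUDED


class GridZoneError(ValueError):
    """A grid coordinate falls in no eccentricity zone (grid/zone mismatch)."""


def assign_zone(x: float, y: float) -> Zone:
    """Sectorise a grid coordinate into inner/middle/outer, or EXCLUDED.

    The blind-spot-adjacent points (15, +/-3) are excluded outright.  For
    every other point the eccentricity, rounded to one decimal place, must
    fall in exactly one of the three zone intervals; a coordinate matching
    none is a hard error because it cannot belong to the 30-2 grid.
    """
    if (x, y) in BLIND_SPOT_ADJACENT:
        return Zone.EXCLUDED
    ecc = round(float(np.hypot(x, y)), 1)
    for name, (lo, hi) in _ZONE_BOUNDS.items():
        if lo <= ecc <= hi:
            return Zone(name)
    raise GridZoneError(
        f"location ({x}, {y}) at eccentricity {ecc} deg lies in no zone; "
        "not a 30-2 grid point"
    )


@dataclass(frozen=True)
class StimulusGrid:
    """The ordered 30-2 lattice in right-eye format.

    Location order is fixed: row-major from the superior field down
    (y = 27 ... -27) and, within each row, temporal to nasal (x descending).
    The order is stable across runs so that sensitivity arrays and exported
    files are byte-comparable.
    """

    locations: tuple[StimulusLocation, ...]
    eye_format: str = "right"

    def __len__(self) -> int:
        return len(self.locations)

    def __iter__(self) -> Iterator[StimulusLocation]:
        return iter(self.locations)

    @property
    def x(self) -> np.ndarray:
        return np.array([p.x for p in self.locations])

    @property
    def y(self) -> np.ndarray:
        return np.array([p.y for p in self.locations])

    @property
    def eccentricity(self) -> np.ndarray:
        return np.array([p.eccentricity for p in self.locations])

    @property
    def zones(self) -> np.ndarray:
        return np.array([p.zone.value for p in self.locations], dtype=object)

    @property
    def analysable_mask(self) -> np.ndarray:
        """Boolean mask of the 74 locations that enter every metric."""
        return np.array([p.analysable for p in self.locations])

    @property
    def n_analysable(self) -> int:
        return int(self.analysable_mask.sum())

    def zone_mask(self, zone: Zone | str) -> np.ndarray:
        zone = Zone(zone)
        return np.array([p.zone is zone for p in self.locations])

    def index_of(self, x: float, y: float) -> int:
        """Canonical index of the location at (x, y)."""
        for i, p in enumerate(self.locations):
            if p.x == x and p.y == y:
                return i
        raise KeyError(f"({x}, {y}) is not a 30-2 location")

    def mirror_index(self) -> np.ndarray:
        """Index array mapping each location to its x-negated counterpart.

        Used to convert a left-eye field into right-eye format: the value
        observed at (x, y) of a left eye belongs at (-x, y) once mirrored.
        """
        idx = np.empty(len(self.locations), dtype=int)
        for i, p in enumerate(self.locations):
            idx[i] = self.index_of(-p.x, p.y)
        return idx

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular export: index, x_deg, y_deg, eccentricity_deg, zone, excluded."""
        return pd.DataFrame(
            {
                "index": np.arange(len(self.locations)),
                "x_deg": self.x,
                "y_deg": self.y,
                "eccentricity_deg": self.eccentricity,
                "zone": self.zones,
                "excluded": (~self.analysable_mask).astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_grid_30_2() -> StimulusGrid:
    """Construct the 76-point 30-2 grid in right-eye format.

    Membership rule: every lattice point (x, y) with |x|, |y| in
    {3, 9, 15, 21, 27} whose eccentricity does not exceed 28.5 degrees.
    This reproduces the standard 76-point pattern; the blind-spot-adjacent
    pair is present but carries zone EXCLUDED.
    """
    locations = []
    for y in sorted(_LATTICE, reverse=True):  # superior -> inferior
        for x in sorted(_LATTICE, reverse=True):  # temporal -> nasal
            ecc = float(np.hypot(x, y))
            if ecc <= _MAX_ECCENTRICITY:
                locations.append(
                    StimulusLocation(
                        x=float(x),
                        y=float(y),
                        eccentricity=ecc,
                        zone=assign_zone(x, y),
                    )
                )
    return StimulusGrid(locations=tuple(locations))


#: Module-level canonical grid; immutable, safe to share.
GRID_30_2 = build_grid_30_2()
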