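"""Humphrey 24-2 test-pattern geometry.

The 24-2 pattern places stimuli on a 6-degree grid offset 3 degrees from the
horizontal and vertical meridians, covering roughly 24 degrees of eccentricity
(27 degrees nasally).  Coordinates here live in a *canonical per-eye frame*
with temporal = +x and superior = +y, so the physiologic blind spot sits at
(15, +/-3) for both eyes and fellow eyes can be pooled without bookkeeping.
Mirroring to the chart frame (the orientation printed on an HVF report, where
nasal is +x for the left eye) happens only at I/O boundaries via
:func:`to_chart_frame` / :func:`from_chart_frame`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Eye",
    "TestLocation",
    "pattern_24_2",
    "to_chart_frame",
    "from_chart_frame",
    "pattern_frame",
    "coords",
    "eccentricities",
    "analyzable_mask",
    "blind_spot_adjacent_mask",
    "N_LOCATIONS",
    "N_ANALYZABLE",
    "BLIND_SPOT_XY",
    "RADIUS_CUTOFF_DEG",
]

#: maximum eccentricity (degrees) for the regular grid portion of the pattern
RADIUS_CUTOFF_DEG = 24.2

#: the two locations falling on the physiologic blind spot (canonical frame)
BLIND_SPOT_XY = ((15, 3), (15, -3))

#: the two nasal-extension points beyond the radius cutoff
_NASAL_XY = ((-27, 3), (-27, -3))

#: grid neighbours of a blind-spot point count as "adjacent" (<= 6.1 deg away)
_BLIND_SPOT_ADJ_RADIUS = 6.1

N_LOCATIONS = 54
N_ANALYZABLE = 52


class Eye(str, enum.Enum):
    """Laterality of an eye."""

    RIGHT = "right"
    LEFT = "left"


@dataclass(frozen=True)
class TestLocation:
    """One 24-2 test location in the canonical per-eye frame.

    Attributes
    ----------
    index:
        Stable identifier, 0..53, in (-y, x) order (superior row first,
        within a row temporal-to-nasal reading order for a right eye).
    x_deg, y_deg:
        Signed coordinates in degrees; odd multiples of 3.
    eccentricity_deg:
        Euclidean distance from fixation.
    is_blind_spot:
        True for the two locations at (15, +/-3).
    """

    index: int
    x_deg: int
    y_deg: int
    eccentricity_deg: float
    is_blind_spot: bool


# The canonical literal pattern, kept alongside the generative rule as a
# guard against derivation bugs; pattern_24_2() asserts the two agree.
_PATTERN_XY = (
    (-9, 21), (-3, 21), (3, 21), (9, 21),
    (-15, 15), (-9, 15), (-3, 15), (3, 15), (9, 15), (15, 15),
    (-21, 9), (-15, 9), (-9, 9), (-3, 9), (3, 9), (9, 9), (15, 9), (21, 9),
    (-27, 3), (-21, 3), (-15, 3), (-9, 3), (-3, 3), (3, 3), (9, 3), (15, 3), (21, 3),
    (-27, -3), (-21, -3), (-15, -3), (-9, -3), (-3, -3), (3, -3), (9, -3), (15, -3), (21, -3),
    (-21, -9), (-15, -9), (-9, -9), (-3, -9), (3, -9), (9, -9), (15, -9), (21, -9),
    (-15, -15), (-9, -15), (-3, -15), (3, -15), (9, -15), (15, -15),
    (-9, -21), (-3, -21), (3, -21), (9, -21),
)


def _derive_xy() -> tuple[tuple[int, int], ...]:
    grid = [v for v in range(-21, 22, 6)]  # odd multiples of 3: -21 .. 21
    pts = [
        (x, y)
        for x in grid
        for y in grid
        if math.hypot(x, y) <= RADIUS_CUTOFF_DEG
    ]
    pts.extend(_NASAL_XY)
    pts.sort(key=lambda p: (-p[1], p[0]))
    return tuple(pts)


@lru_cache(maxsize=1)
def pattern_24_2() -> tuple[TestLocation, ...]:
    """Return the 54 locations of the 24-2 pattern in canonical order.

    The set is all (x, y) with x, y odd multiples of 3 within 21 degrees and
    sqrt(x^2 + y^2) <= 24.2, plus the two nasal-extension points (-27, +/-3).
    Ordering is by (-y, x): superior rows first, left to right.
    """
    derived = _derive_xy()
    assert derived == _PATTERN_XY, "24-2 derivation disagrees with literal table"
    bs = set(BLIND_SPOT_XY)
    return tuple(
        TestLocation(
            index=i,
            x_deg=x,
            y_deg=y,
            eccentricity_deg=math.hypot(x, y),
            is_blind_spot=(x, y) in bs,
        )
        for i, (x, y) in enumerate(derived)
    )


def to_chart_frame(loc: TestLocation | tuple[float, float], eye: Eye) -> tuple[float, float]:
    """Map canonical (temporal = +x) coordinates to the printed chart frame.

    For a right eye the frames coincide; for a left eye x is negated.  The
    conversion is its own inverse.
    """
    x, y = (loc.x_deg, loc.y_deg) if isinstance(loc, TestLocation) else loc
    if Eye(eye) is Eye.LEFT:
        return (-x, y)
    return (x, y)


def from_chart_frame(xy: tuple[float, float], eye: Eye) -> tuple[float, float]:
    """Inverse of :func:`to_chart_frame` (identical map; mirroring is an involution)."""
    return to_chart_frame(xy, eye)


def coords() -> np.ndarray:
    """(54, 2) array of canonical (x, y) in pattern order."""
    return np.array([(l.x_deg, l.y_deg) for l in pattern_24_2()], dtype=float)


def eccentricities() -> np.ndarray:
    """(54,) array of eccentricities in degrees."""
    return np.array([l.eccentricity_deg for l in pattern_24_2()])


def analyzable_mask() -> np.ndarray:
    """(54,) boolean mask, True for the 52 non-blind-spot locations."""
    return np.array([not l.is_blind_spot for l in pattern_24_2()])


def blind_spot_adjacent_mask() -> np.ndarray:
    """(54,) mask of non-blind-spot locations within 6.1 deg of a blind-spot point.

    Exactly six grid locations qualify; they ring the physiologic scotoma and
    are where papilledema-related loss concentrates.
    """
    xy = coords()
    out = np.zeros(len(xy), dtype=bool)
    for bx, by in BLIND_SPOT_XY:
        d = np.hypot(xy[:, 0] - bx, xy[:, 1] - by)
        out |= d <= _BLIND_SPOT_ADJ_RADIUS
    return out & analyzable_mask()


def pattern_frame() -> pd.DataFrame:
    """The pattern as a tidy table: index, x_deg, y_deg, eccentricity_deg, is_blind_spot."""
    return pd.DataFrame(
        {
            "index": [l.index for l in pattern_24_2()],
            "x_deg": [l.x_deg for l in pattern_24_2()],
            "y_deg": [l.y_deg for l in pattern_24_2()],
            "eccentricity_deg": [l.eccentricity_deg for l in pattern_24_2()],
            "is_blind_spot": [l.is_blind_spot for l in pattern_24_2()],
        }
    )


def export_pattern_csv(path) -> None:
    """Write the pattern table to CSV."""
    pattern_frame().to_csv(path, index=False)


def location_index(x_deg: float, y_deg: float) -> int:
    """Canonical-frame (x, y) -> pattern index; KeyError if not a 24-2 location."""
    return _xy_to_index()[(int(x_deg), int(y_deg))]


@lru_cache(maxsize=1)
def _xy_to_index() -> dict[tuple[int, int], int]:
    return {(l.x_deg, l.y_deg): l.index for l in pattern_24_2()}
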