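"""Perimetric test grids and the coordinate conventions used throughout.

All fields are stored in a single reference-eye orientation: the blind-spot
column sits at ``x = +15`` and the two far-nasal extension points at
``x = -27``.  Left eyes are mirrored onto this convention on ingest (see
:func:`vfarch.fields.mirror_to_reference_eye`).

Locations lie on a 6-degree lattice offset by 3 degrees from the meridians,
ordered row-major: top row first, left to right within a row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator

import numpy as np

P24_2 = "P24_2"
SMP_44 = "SMP_44"
COMMON_42 = "COMMON_42"

GRID_NAMES = (P24_2, SMP_44, COMMON_42)

#: x column of the physiologic blind spot (reference-eye convention).
BLIND_SPOT_X = 15
#: x column of the two far-nasal extension points of the full grid.
NASAL_EXTENSION_X = -27

# Half-width of each lattice row, keyed by |y|.  Rows at |y| = 3 additionally
# carry the nasal extension point at x = -27.
_ROW_HALF_WIDTH = {21: 9, 15: 15, 9: 21, 3: 21}

_ROW_YS = (21, 15, 9, 3, -3, -9, -15, -21)


class UnknownGridError(ValueError):
    """Raised when a grid name is not one of the canonical grid names."""


class GridMismatchError(ValueError):
    """Raised when an operation receives fields/references on unequal grids."""


@dataclass(frozen=True)
class GridLocation:
    """A single test location in degrees of visual angle."""

    x_deg: int
    y_deg: int
    is_blind_spot: bool = False

    def __post_init__(self) -> None:
        if abs(self.x_deg) not in (3, 9, 15, 21, 27) or abs(self.y_deg) not in (3, 9, 15, 21):
            raise ValueError(
                f"({self.x_deg}, {self.y_deg}) is not on the 6-degree lattice offset by 3"
            )


@dataclass(frozen=True)
class TestGrid:
    """An ordered, named set of test locations.

    Ordering is canonical (row-major, top row first, left to right) and is
    identical for every field compared downstream.
    """

    name: str
    locations: tuple[GridLocation, ...]

    def __len__(self) -> int:
        return len(self.locations)

    def __iter__(self) -> Iterator[GridLocation]:
        return iter(self.locations)

    @property
    def x(self) -> np.ndarray:
        return np.array([loc.x_deg for loc in self.locations])

    @property
    def y(self) -> np.ndarray:
        return np.array([loc.y_deg for loc in self.locations])

    def index_of(self, x_deg: int, y_deg: int) -> int:
        """Index of the location at ``(x_deg, y_deg)``; KeyError if absent."""
        try:
            return self._coord_index()[(x_deg, y_deg)]
        except KeyError:
            raise KeyError(f"({x_deg}, {y_deg}) not in grid {self.name}") from None

    def _coord_index(self) -> dict[tuple[int, int], int]:
        # frozen dataclass: cache on the instance dict via object.__setattr__
        cached = self.__dict__.get("_coord_cache")
        if cached is None:
            cached = {(l.x_deg, l.y_deg): i for i, l in enumerate(self.locations)}
            object.__setattr__(self, "_coord_cache", cached)
        return cached

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "locations": [[l.x_deg, l.y_deg, l.is_blind_spot] for l in self.locations],
        }
        return json.dumps(payload)

    @staticmethod
    def from_json(text: str) -> "TestGrid":
        payload = json.loads(text)
        locs = tuple(GridLocation(x, y, bool(bs)) for x, y, bs in payload["locations"])
        return TestGrid(payload["name"], locs)


def _full_lattice() -> tuple[GridLocation, ...]:
    locs: list[GridLocation] = []
    for y in _ROW_YS:
        half = _ROW_HALF_WIDTH[abs(y)]
        xs = [x for x in range(-21, 22, 6) if abs(x) <= half]
        if abs(y) == 3:
            xs = [NASAL_EXTENSION_X] + xs
        for x in xs:
            locs.append(
                GridLocation(x, y, is_blind_spot=(x == BLIND_SPOT_X and abs(y) == 3))
            )
    return tuple(locs)


@lru_cache(maxsize=None)
def build_grid(name: str) -> TestGrid:
    """Construct one of the canonical grids.

    ``P24_2`` is the full 54-location lattice; ``SMP_44`` drops the top and
    bottom rows (y = ±21) and the two nasal extension points; ``COMMON_42``
    further drops the two blind-spot locations and is the location set every
    cross-modality comparison runs on.
    """
    if name not in GRID_NAMES:
        raise UnknownGridError(f"unknown grid name {name!r}; expected one of {GRID_NAMES}")
    full = _full_lattice()
    if name == P24_2:
        return TestGrid(P24_2, full)
    smp = tuple(
        l for l in full if abs(l.y_deg) != 21 and l.x_deg != NASAL_EXTENSION_X
    )
    if name == SMP_44:
        return TestGrid(SMP_44, smp)
    return TestGrid(COMMON_42, tuple(l for l in smp if not l.is_blind_spot))


def mirror_permutation(grid: TestGrid) -> np.ndarray:
    """Index permutation implementing the left/right mirror on a full grid.

    Within every lattice row the canonical x list and its negation are
    reverses of one another, so mirroring a field is a per-row positional
    reversal.  Only defined for the full acquisition grids: the analysis set
    COMMON_42 is not x-symmetric (one blind-spot column is missing).
    """
    if grid.name == COMMON_42:
        raise GridMismatchError("mirroring is defined on full acquisition grids only")
    perm = np.empty(len(grid), dtype=int)
    y = grid.y
    for row_y in np.unique(y):
        idx = np.flatnonzero(y == row_y)
        perm[idx] = idx[::-1]
    return perm


def common_subset_indices(grid: TestGrid) -> np.ndarray:
    """Indices of ``grid`` locations retained in COMMON_42, in canonical order."""
    common = build_grid(COMMON_42)
    return np.array([grid.index_of(l.x_deg, l.y_deg) for l in common])
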