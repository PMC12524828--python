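"""Visual field data model, orientation handling and the long-format CSV dialect."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .grids import (
    COMMON_42,
    GRID_NAMES,
    GridMismatchError,
    TestGrid,
    build_grid,
    common_subset_indices,
    mirror_permutation,
)

SAP_III = "SAP_III"
SMP = "SMP"
MODALITIES = (SAP_III, SMP)

RIGHT = "right"
LEFT = "left"

ABSOLUTE = "absolute"
CHANGE = "change"

#: Long-format field CSV columns (one row per test location).  ``replicate``
#: is an optional extra column disambiguating same-day repeat tests.
FIELD_CSV_COLUMNS = [
    "eye_id",
    "visit_index",
    "age_years",
    "laterality",
    "modality",
    "x_deg",
    "y_deg",
    "value_db",
]


@dataclass
class VisualField:
    """Raw sensitivities of one eye / visit / modality on a canonical grid."""

    eye_id: str
    visit_index: int
    age_years: float
    modality: str
    grid: TestGrid
    values_db: np.ndarray
    laterality: str = RIGHT
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values_db = np.asarray(self.values_db, dtype=float)
        _validate_common(self)
        if np.any(self.values_db < 0):
            raise ValueError("sensitivities must be >= 0 dB")

    def replace_values(self, values_db: np.ndarray, **meta) -> "VisualField":
        new = dataclasses.replace(self, values_db=np.asarray(values_db, dtype=float))
        new.meta = {**self.meta, **meta}
        return new


@dataclass
class TDField:
    """Total-deviation map (dB, negative = deficit).

    ``kind`` is ``"absolute"`` for plain TD maps and ``"change"`` for
    follow-up-minus-baseline maps, where positive values indicate improvement
    and negative values deterioration.
    """

    eye_id: str
    visit_index: int
    age_years: float
    modality: str
    grid: TestGrid
    values_db: np.ndarray
    kind: str = ABSOLUTE
    laterality: str = RIGHT
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values_db = np.asarray(self.values_db, dtype=float)
        _validate_common(self)
        if self.kind not in (ABSOLUTE, CHANGE):
            raise ValueError(f"unknown TD kind {self.kind!r}")

    def replace_values(self, values_db: np.ndarray, **meta) -> "TDField":
        new = dataclasses.replace(self, values_db=np.asarray(values_db, dtype=float))
        new.meta = {**self.meta, **meta}
        return new


def _validate_common(f) -> None:
    if f.modality not in MODALITIES:
        raise ValueError(f"unknown modality {f.modality!r}; expected one of {MODALITIES}")
    if f.laterality not in (RIGHT, LEFT):
        raise ValueError(f"laterality must be {RIGHT!r} or {LEFT!r}")
    if int(f.visit_index) != f.visit_index or f.visit_index < 0:
        raise ValueError("visit_index must be a nonnegative integer")
    f.visit_index = int(f.visit_index)
    if f.values_db.ndim != 1 or len(f.values_db) != len(f.grid):
        raise ValueError(
            f"expected {len(f.grid)} values for grid {f.grid.name}, got {f.values_db.shape}"
        )
    if not np.all(np.isfinite(f.values_db)):
        raise ValueError("field values must be finite")


def mirror_to_reference_eye(field, laterality: str | None = None):
    """Mirror a field into the reference-eye orientation.

    Right-eye fields are returned unchanged.  For left eyes, the value stored
    at native location ``(x, y)`` ends up at canonical ``(-x, y)``; on the
    full grids this is a per-row positional reversal and an involution.
    """
    lat = field.laterality if laterality is None else laterality
    if lat == RIGHT:
        return field
    if lat != LEFT:
        raise ValueError(f"laterality must be {RIGHT!r} or {LEFT!r}")
    perm = mirror_permutation(field.grid)
    return field.replace_values(field.values_db[perm])


def align_to_common(field):
    """Restrict a field to the 42-location analysis set, canonical order.

    Drops the peripheral rows / nasal extension (full 24-2 input) and the two
    blind-spot locations; values at retained locations are unchanged.
    """
    if field.grid.name not in GRID_NAMES:
        raise GridMismatchError(f"unrecognized grid {field.grid.name!r}")
    if field.grid.name == COMMON_42:
        return field
    idx = common_subset_indices(field.grid)
    return dataclasses.replace(
        field,
        values_db=field.values_db[idx],
        grid=build_grid(COMMON_42),
        meta=dict(field.meta),
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def fields_to_frame(fields) -> pd.DataFrame:
    """Long-format table of fields, written in each eye's native orientation."""
    rows = []
    for f in fields:
        sign = -1 if f.laterality == LEFT else 1
        rep = f.meta.get("replicate", 0)
        for loc, v in zip(f.grid, f.values_db):
            rows.append(
                (
                    f.eye_id,
                    f.visit_index,
                    f.age_years,
                    f.laterality,
                    f.modality,
                    sign * loc.x_deg,
                    loc.y_deg,
                    v,
                    rep,
                )
            )
    return pd.DataFrame(rows, columns=FIELD_CSV_COLUMNS + ["replicate"])


def write_fields_csv(fields, path, header_comment: str | None = None) -> None:
    frame = fields_to_frame(fields)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False, float_format="%.6f")


def read_fields_csv(path) -> list:
    """Read a long-format field CSV; left eyes are mirrored on ingest."""
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in FIELD_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"field CSV missing required columns: {missing}")
    if "replicate" not in frame.columns:
        frame = frame.assign(replicate=0)
    fields = []
    keys = ["eye_id", "visit_index", "modality", "replicate"]
    for (eye, visit, modality, rep), grp in frame.groupby(keys, sort=True):
        lats = grp["laterality"].unique()
        if len(lats) != 1:
            raise ValueError(f"mixed laterality within field {eye}/{visit}/{modality}")
        lat = lats[0]
        sign = -1 if lat == LEFT else 1
        grid = _infer_grid(len(grp))
        values = np.full(len(grid), np.nan)
        for row in grp.itertuples(index=False):
            i = grid.index_of(sign * int(row.x_deg), int(row.y_deg))
            values[i] = row.value_db
        if np.any(np.isnan(values)):
            raise ValueError(
                f"field {eye}/{visit}/{modality} does not cover grid {grid.name}"
            )
        ages = grp["age_years"].unique()
        fields.append(
            VisualField(
                eye_id=str(eye),
                visit_index=int(visit),
                age_years=float(ages[0]),
                modality=str(modality),
                grid=grid,
                values_db=values,
                laterality=str(lat),
                meta={"replicate": int(rep)},
            )
        )
    return fields


def _infer_grid(n_locations: int) -> TestGrid:
    by_size = {54: "P24_2", 44: "SMP_44", 42: COMMON_42}
    if n_locations not in by_size:
        raise ValueError(f"cannot infer grid from {n_locations} locations")
    return build_grid(by_size[n_locations])
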