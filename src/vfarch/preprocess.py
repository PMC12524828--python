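"""Raw sensitivities -> analysis-ready total-deviation matrices.

Fixed pipeline order: censor (size III only) -> same-day replicate average ->
age-standardize to 45 years -> total deviation -> align to the 42-location
analysis set.  The absolute analysis (AVFA) uses every TD field; the change
analysis (VFCA) subtracts each eye's baseline (visit 0) from every later
visit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .fields import ABSOLUTE, CHANGE, SAP_III, MODALITIES, TDField, VisualField, align_to_common
from .grids import COMMON_42, GridMismatchError, TestGrid, build_grid

log = logging.getLogger(__name__)


@dataclass
class NormativeReference:
    """Per-location normal mean sensitivity at age 45 plus aging slope.

    ``slope_db_per_year`` is the expected sensitivity *decline* per year of
    age (a nonnegative number).
    """

    modality: str
    grid: TestGrid
    mean45_db: np.ndarray
    slope_db_per_year: np.ndarray
    reference_age_years: float = 45.0

    def __post_init__(self) -> None:
        self.mean45_db = np.asarray(self.mean45_db, dtype=float)
        self.slope_db_per_year = np.asarray(self.slope_db_per_year, dtype=float)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        for arr, name in ((self.mean45_db, "mean45_db"), (self.slope_db_per_year, "slope")):
            if arr.shape != (len(self.grid),):
                raise GridMismatchError(f"{name} must have one entry per grid location")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
        if np.any(self.slope_db_per_year < 0):
            raise ValueError("slope_db_per_year must be >= 0")


@dataclass
class PreprocessConfig:
    censor_floor_db: float = 20.0
    reference_age_years: float = 45.0
    #: modalities whose raw sensitivities are censored at the floor
    censor_modalities: tuple = (SAP_III,)

    def __post_init__(self) -> None:
        if not 0.0 <= self.censor_floor_db <= 40.0:
            raise ValueError("censor_floor_db must lie within [0, 40]")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def censor(field: VisualField, floor_db: float) -> VisualField:
    """Replace sensitivities below ``floor_db`` with the floor.

    The fraction of censored locations is recorded in ``meta['censored_fraction']``.
    """
    values = np.maximum(field.values_db, floor_db)
    frac = float(np.mean(field.values_db < floor_db))
    return field.replace_values(values, censored_fraction=frac, censor_floor_db=floor_db)


def age_standardize(
    field: VisualField, ref: NormativeReference, reference_age: float = 45.0
) -> VisualField:
    """Linearly correct sensitivities to the reference age.

    value' = value + slope * (age - reference_age); the output field's age is
    set to ``reference_age``.  Results are floored at 0 dB (sensitivities are
    nonnegative by definition); the clip only matters at the measurement floor.
    """
    if ref.grid.name != field.grid.name:
        raise GridMismatchError(
            f"reference grid {ref.grid.name} != field grid {field.grid.name}"
        )
    offset = ref.slope_db_per_year * (field.age_years - reference_age)
    new = field.replace_values(np.maximum(field.values_db + offset, 0.0))
    new.age_years = reference_age
    return new


def to_total_deviation(field: VisualField, ref: NormativeReference) -> TDField:
    """Total deviation: age-standardized sensitivity minus the normal mean."""
    if ref.grid.name != field.grid.name:
        raise GridMismatchError(
            f"reference grid {ref.grid.name} != field grid {field.grid.name}"
        )
    return TDField(
        eye_id=field.eye_id,
        visit_index=field.visit_index,
        age_years=field.age_years,
        modality=field.modality,
        grid=field.grid,
        values_db=field.values_db - ref.mean45_db,
        kind=ABSOLUTE,
        laterality=field.laterality,
        meta=dict(field.meta),
    )


def average_same_day(fields: list) -> VisualField:
    """Pointwise mean of same-day replicate tests of one eye/visit/modality."""
    if not fields:
        raise ValueError("cannot average an empty list of fields")
    first = fields[0]
    for f in fields[1:]:
        if (f.eye_id, f.visit_index, f.modality, f.grid.name) != (
            first.eye_id,
            first.visit_index,
            first.modality,
            first.grid.name,
        ):
            raise ValueError("same-day averaging requires one eye/visit/modality/grid")
    values = np.mean([f.values_db for f in fields], axis=0)
    fracs = [f.meta["censored_fraction"] for f in fields if "censored_fraction" in f.meta]
    new = first.replace_values(values, n_replicates=len(fields))
    if fracs:
        new.meta["censored_fraction"] = float(np.mean(fracs))
    new.age_years = float(np.mean([f.age_years for f in fields]))
    return new


def change_map(baseline: TDField, followup: TDField) -> TDField:
    """Follow-up minus baseline TD map (positive = improvement)."""
    if (baseline.eye_id, baseline.modality, baseline.grid.name) != (
        followup.eye_id,
        followup.modality,
        followup.grid.name,
    ):
        raise ValueError("change maps require matching eye, modality and grid")
    if baseline.kind != ABSOLUTE or followup.kind != ABSOLUTE:
        raise ValueError("change maps are built from absolute TD fields")
    if baseline.visit_index != 0 or followup.visit_index <= 0:
        raise ValueError("baseline must be visit 0 and follow-up a later visit")
    return dataclasses.replace(
        followup,
        values_db=followup.values_db - baseline.values_db,
        kind=CHANGE,
        meta=dict(followup.meta),
    )


def build_change_fields(fields: list) -> list:
    """Subtract each eye's baseline from all its later visits, per modality.

    Eyes without a visit-0 record are excluded with a logged warning.
    """
    out: list[TDField] = []
    by_eye: dict[tuple, list] = {}
    for f in fields:
        by_eye.setdefault((f.eye_id, f.modality), []).append(f)
    for (eye, modality), group in sorted(by_eye.items()):
        group = sorted(group, key=lambda f: f.visit_index)
        if group[0].visit_index != 0:
            log.warning("eye %s/%s has no baseline visit; excluded from VFCA", eye, modality)
            continue
        baseline = group[0]
        out.extend(change_map(baseline, f) for f in group[1:])
    return out


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

def _build_matrix(fields: list, kind: str):
    if not fields:
        raise ValueError("cannot build a matrix from zero fields")
    modality = fields[0].modality
    for f in fields:
        if f.kind != kind:
            raise ValueError(f"expected only kind={kind!r} fields, got {f.kind!r}")
        if f.modality != modality:
            raise ValueError("matrix rows must share one modality")
        if f.grid.name != COMMON_42:
            raise GridMismatchError("matrix rows must be on the COMMON_42 analysis grid")
    ordered = sorted(fields, key=lambda f: (f.eye_id, f.visit_index))
    X = np.vstack([f.values_db for f in ordered])
    index = pd.DataFrame(
        {
            "eye_id": [f.eye_id for f in ordered],
            "visit_index": [f.visit_index for f in ordered],
            "modality": [f.modality for f in ordered],
        }
    )
    return X, index


def build_avfa_matrix(fields: list):
    """n x 42 matrix of absolute TD fields (one modality) plus a row index."""
    return _build_matrix(fields, ABSOLUTE)


def build_vfca_matrix(fields: list):
    """n x 42 matrix of change TD fields (one modality) plus a row index."""
    return _build_matrix(fields, CHANGE)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def preprocess_fields(
    raw_fields: list,
    references: dict,
    config: PreprocessConfig | None = None,
) -> dict:
    """Run the fixed preprocessing order on raw fields of both modalities.

    ``references`` maps modality -> :class:`NormativeReference` on that
    modality's native acquisition grid.  Returns modality -> list of absolute
    TD fields on COMMON_42.
    """
    config = config or PreprocessConfig()
    groups: dict[tuple, list] = {}
    for f in raw_fields:
        if f.modality in config.censor_modalities:
            f = censor(f, config.censor_floor_db)
        groups.setdefault((f.eye_id, f.visit_index, f.modality), []).append(f)

    out: dict[str, list] = {}
    for (eye, visit, modality), replicates in sorted(groups.items()):
        ref = references.get(modality)
        if ref is None:
            raise KeyError(f"no normative reference supplied for modality {modality}")
        f = average_same_day(replicates)
        f = age_standardize(f, ref, config.reference_age_years)
        td = to_total_deviation(f, ref)
        out.setdefault(modality, []).append(align_to_common(td))
    for modality, tds in out.items():
        fracs = [t.meta.get("censored_fraction") for t in tds]
        fracs = [x for x in fracs if x is not None]
        if fracs:
            log.info("%s: mean censored fraction %.3f over %d fields", modality, float(np.mean(fracs)), len(tds))
    return out


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

NORMATIVE_CSV_COLUMNS = ["modality", "x_deg", "y_deg", "mean45_db", "slope_db_per_year"]


def write_normative_csv(references: dict, path, header_comment: str | None = None) -> None:
    rows = []
    for modality in sorted(references):
        ref = references[modality]
        for loc, m, s in zip(ref.grid, ref.mean45_db, ref.slope_db_per_year):
            rows.append((modality, loc.x_deg, loc.y_deg, m, s))
    frame = pd.DataFrame(rows, columns=NORMATIVE_CSV_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False, float_format="%.6f")


def read_normative_csv(path) -> dict:
    """Read a normative CSV into modality -> :class:`NormativeReference`."""
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in NORMATIVE_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"normative CSV missing required columns: {missing}")
    out = {}
    for modality, grp in frame.groupby("modality", sort=True):
        from .fields import _infer_grid

        grid = _infer_grid(len(grp))
        mean45 = np.full(len(grid), np.nan)
        slope = np.full(len(grid), np.nan)
        for row in grp.itertuples(index=False):
            i = grid.index_of(int(row.x_deg), int(row.y_deg))
            mean45[i] = row.mean45_db
            slope[i] = row.slope_db_per_year
        out[str(modality)] = NormativeReference(str(modality), grid, mean45, slope)
    return out


def _value_column(loc) -> str:
    return f"x{loc.x_deg}y{loc.y_deg}"


def write_matrix_csv(X: np.ndarray, index: pd.DataFrame, grid: TestGrid, path,
                     header_comment: str | None = None) -> None:
    """Matrix CSV: row-identity columns followed by one column per location."""
    cols = [_value_column(loc) for loc in grid]
    frame = pd.concat([index.reset_index(drop=True), pd.DataFrame(X, columns=cols)], axis=1)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False, float_format="%.6f")


def read_matrix_csv(path):
    frame = pd.read_csv(path, comment="#")
    grid = build_grid(COMMON_42)
    cols = [_value_column(loc) for loc in grid]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"matrix CSV missing value columns: {missing[:3]}...")
    X = frame[cols].to_numpy(dtype=float)
    index = frame[["eye_id", "visit_index", "modality"]].copy()
    return X, index
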