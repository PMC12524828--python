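"""Synthetic paired SAP-III / SMP cohorts with known ground truth.

Each eye carries a planted total-deviation pattern: a Dirichlet-weighted
convex mixture of named defect templates, scaled by a lognormal severity, and
progressed linearly along the (unit-depth) defect direction across 6-monthly
visits.  Both modalities observe the *same* latent TD surface; observation
noise is heteroscedastic for SAP-III (SD grows with local defect depth) and
flat for SMP.  A hill-of-vision normative surface with a known aging slope
makes every preprocessing step exactly invertible in tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import LEFT, RIGHT, SAP_III, SMP, VisualField
from .grids import COMMON_42, P24_2, SMP_44, TestGrid, build_grid, common_subset_indices
from .preprocess import NormativeReference

TEMPLATE_NAMES = (
    "normal",
    "superior_arcuate",
    "inferior_arcuate",
    "superior_nasal_step",
    "inferior_nasal_step",
    "paracentral",
    "diffuse",
    "temporal_wedge",
)

#: depth (positive dB) that every focal defect template is normalized to
TEMPLATE_DEPTH_DB = 12.0

# generating hill-of-vision surfaces: peak at fixation, linear eccentricity decay
_SURFACE = {
    SAP_III: {"peak_db": 33.0, "falloff_db_per_deg": 0.15},
    SMP: {"peak_db": 30.0, "falloff_db_per_deg": 0.10},
}
#: known aging slope of the generating surfaces, dB per year
GENERATING_AGE_SLOPE = 0.06

_NATIVE_GRID = {SAP_III: P24_2, SMP: SMP_44}


@dataclass(frozen=True)
class ArchetypeTemplate:
    name: str
    td_pattern: np.ndarray  # <= 0, one value per COMMON_42 location


@dataclass
class CohortConfig:
    n_eyes: int = 83
    visits_per_eye: int = 4
    mixture_concentration: float = 0.5
    severity_median_db: float = 8.0
    severity_sigma: float = 0.4
    progression_rate_mean: float = -0.5   # dB/yr at the deepest defect point
    progression_rate_sd: float = 0.25
    sap_noise_floor_sd: float = 1.0
    sap_noise_slope: float = 0.15         # extra SD per dB of local deficit
    smp_noise_sd: float = 1.2
    visit_interval_years: float = 0.5
    baseline_age_mean: float = 66.7
    baseline_age_sd: float = 9.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 1 or self.visits_per_eye < 1:
            raise ValueError("n_eyes and visits_per_eye must be >= 1")
        for name in (
            "severity_sigma",
            "progression_rate_sd",
            "sap_noise_floor_sd",
            "sap_noise_slope",
            "smp_noise_sd",
            "baseline_age_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mixture_concentration <= 0:
            raise ValueError("mixture_concentration must be > 0")
        if self.severity_median_db <= 0:
            raise ValueError("severity_median_db must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    template_names: list
    templates: np.ndarray       # n_templates x 42
    weights: np.ndarray         # n_eyes x n_templates, rows on the simplex
    severities: np.ndarray
    rates_db_per_year: np.ndarray
    baseline_ages: np.ndarray
    lateralities: list
    config: CohortConfig

    def planted_td(self, eye: int, visit: int = 0) -> np.ndarray:
        """Latent TD surface of one eye at one visit, on COMMON_42."""
        mix = self.weights[eye] @ self.templates
        t0 = (self.severities[eye] / TEMPLATE_DEPTH_DB) * mix
        depth = -t0.min()
        pattern = (-t0 / depth) if depth > 1e-9 else np.zeros_like(t0)
        years = visit * self.config.visit_interval_years
        return t0 + years * self.rates_db_per_year[eye] * pattern

    def to_json(self) -> str:
        payload = {
            "template_names": list(self.template_names),
            "templates": self.templates.tolist(),
            "weights": self.weights.tolist(),
            "severities": self.severities.tolist(),
            "rates_db_per_year": self.rates_db_per_year.tolist(),
            "baseline_ages": self.baseline_ages.tolist(),
            "lateralities": list(self.lateralities),
            "config": self.config.to_dict(),
            "seed": self.config.seed,
        }
        return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def _normalize_depth(raw: np.ndarray) -> np.ndarray:
    return -TEMPLATE_DEPTH_DB * raw / raw.max()


def make_templates(grid: TestGrid | None = None) -> list[ArchetypeTemplate]:
    """The eight named defect morphologies on the 42-location analysis grid.

    The normal template is identically zero; every focal template has depth
    12 dB and keeps at least 60% of locations shallower than 2 dB.  Superior
    and inferior variants are exact mirror images under ``y -> -y``.
    """
    grid = grid or build_grid(COMMON_42)
    x = grid.x.astype(float)
    y = grid.y.astype(float)
    r = np.hypot(x, y)

    def arcuate(sign: float) -> np.ndarray:
        raw = np.exp(-(((r - 15.0) / 4.0) ** 2)) * (sign * y > 0)
        return _normalize_depth(raw)

    def nasal_step(sign: float) -> np.ndarray:
        raw = np.exp(-(((x + 21.0) / 8.0) ** 2) - (((sign * y - 3.0) / 6.0) ** 2))
        raw = raw * (sign * y > 0)
        return _normalize_depth(raw)

    paracentral = _normalize_depth(np.exp(-(((x + 3.0) ** 2) + ((y - 3.0) ** 2)) / 36.0))
    wedge = _normalize_depth(np.exp(-(((x - 21.0) ** 2) / 50.0) - (y ** 2) / 72.0))

    patterns = {
        "normal": np.zeros(len(grid)),
        "superior_arcuate": arcuate(+1.0),
        "inferior_arcuate": arcuate(-1.0),
        "superior_nasal_step": nasal_step(+1.0),
        "inferior_nasal_step": nasal_step(-1.0),
        "paracentral": paracentral,
        "diffuse": np.full(len(grid), -10.0),
        "temporal_wedge": wedge,
    }
    return [ArchetypeTemplate(name, patterns[name]) for name in TEMPLATE_NAMES]


# ---------------------------------------------------------------------------
# Normative simulation
# ---------------------------------------------------------------------------

def generating_reference(modality: str, grid: TestGrid | None = None) -> NormativeReference:
    """The exact (noise-free) normative surface used by the generator."""
    grid = grid or build_grid(_NATIVE_GRID[modality])
    surf = _SURFACE[modality]
    r = np.hypot(grid.x.astype(float), grid.y.astype(float))
    mean45 = surf["peak_db"] - surf["falloff_db_per_deg"] * r
    slope = np.full(len(grid), GENERATING_AGE_SLOPE)
    return NormativeReference(modality, grid, mean45, slope)


def estimate_reference(fields: list, modality: str) -> NormativeReference:
    """Estimate a normative reference from healthy fields.

    The aging slope is pooled across locations (one slope; the generator's
    slope is spatially constant), then per-location means are taken after
    age-standardizing every field to 45 years with the pooled slope.
    """
    fields = [f for f in fields if f.modality == modality]
    if len(fields) < 2:
        raise ValueError("need at least two healthy fields to estimate a reference")
    grid = fields[0].grid
    V = np.vstack([f.values_db for f in fields])        # m x p
    ages = np.array([f.age_years for f in fields])
    a = ages - ages.mean()
    denom = float(np.sum(a ** 2))
    if denom <= 0:
        slope_est = 0.0
    else:
        centered = V - V.mean(axis=0)
        slope_est = max(0.0, -float(np.sum(a[:, None] * centered) / (V.shape[1] * denom)))
    mean45 = (V + slope_est * (ages - 45.0)[:, None]).mean(axis=0)
    return NormativeReference(modality, grid, mean45, np.full(len(grid), slope_est))


def simulate_normative(
    modality: str,
    n_subjects: int = 60,
    tests_per_subject: int = 2,
    seed: int = 0,
    noise_sd: float = 1.0,
    age_range: tuple = (20.0, 80.0),
) -> tuple[NormativeReference, list]:
    """Simulate a healthy normative cohort and the reference estimated from it."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    modality_key = int.from_bytes(modality.encode("utf-8"), "little") % (2 ** 31)
    rng = np.random.default_rng(np.random.SeedSequence([seed, modality_key]))
    true_ref = generating_reference(modality)
    grid = true_ref.grid
    fields = []
    for s in range(n_subjects):
        age = float(rng.uniform(*age_range))
        for t in range(tests_per_subject):
            sens = (
                true_ref.mean45_db
                - true_ref.slope_db_per_year * (age - 45.0)
                + rng.normal(0.0, 1.0, len(grid)) * noise_sd
            )
            fields.append(
                VisualField(
                    eye_id=f"healthy{s:03d}",
                    visit_index=t,
                    age_years=age,
                    modality=modality,
                    grid=grid,
                    values_db=np.maximum(sens, 0.0),
                )
            )
    return estimate_reference(fields, modality), fields


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: CohortConfig, templates: list | None = None
) -> tuple[list, GroundTruth]:
    """Paired longitudinal SAP-III / SMP fields plus the planted ground truth.

    Returns ``n_eyes * visits_per_eye * 2`` raw :class:`VisualField` records
    on the modality-native grids (reference-eye orientation; laterality
    alternates by eye and only affects how fields serialize).
    """
    templates = templates if templates is not None else make_templates()
    T = np.vstack([t.td_pattern for t in templates])
    n_templates = T.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed]))

    refs = {m: generating_reference(m) for m in (SAP_III, SMP)}
    embed = {m: common_subset_indices(refs[m].grid) for m in (SAP_III, SMP)}

    weights = np.empty((config.n_eyes, n_templates))
    severities = np.empty(config.n_eyes)
    rates = np.empty(config.n_eyes)
    ages0 = np.empty(config.n_eyes)
    lats = []
    fields: list[VisualField] = []

    for e in range(config.n_eyes):
        lat = RIGHT if e % 2 == 0 else LEFT
        lats.append(lat)
        ages0[e] = float(
            np.clip(rng.normal(config.baseline_age_mean, config.baseline_age_sd), 40.0, 90.0)
        )
        weights[e] = rng.dirichlet(np.full(n_templates, config.mixture_concentration))
        severities[e] = float(
            rng.lognormal(np.log(config.severity_median_db), config.severity_sigma)
        )
        rates[e] = float(rng.normal(config.progression_rate_mean, config.progression_rate_sd))

        mix = weights[e] @ T
        t0 = (severities[e] / TEMPLATE_DEPTH_DB) * mix
        depth = -t0.min()
        pattern = (-t0 / depth) if depth > 1e-9 else np.zeros_like(t0)

        for m in range(config.visits_per_eye):
            years = m * config.visit_interval_years
            t_m = t0 + years * rates[e] * pattern
            age = ages0[e] + years
            for modality in (SAP_III, SMP):
                ref = refs[modality]
                td_full = np.zeros(len(ref.grid))
                td_full[embed[modality]] = t_m
                if modality == SAP_III:
                    sd = config.sap_noise_floor_sd + config.sap_noise_slope * np.maximum(
                        0.0, -td_full
                    )
                else:
                    sd = np.full(len(ref.grid), config.smp_noise_sd)
                noise = rng.normal(0.0, 1.0, len(ref.grid)) * sd
                sens = (
                    ref.mean45_db
                    - ref.slope_db_per_year * (age - 45.0)
                    + td_full
                    + noise
                )
                fields.append(
                    VisualField(
                        eye_id=f"eye{e:03d}",
                        visit_index=m,
                        age_years=age,
                        modality=modality,
                        grid=ref.grid,
                        values_db=np.maximum(sens, 0.0),
                        laterality=lat,
                    )
                )

    truth = GroundTruth(
        template_names=[t.name for t in templates],
        templates=T,
        weights=weights,
        severities=severities,
        rates_db_per_year=rates,
        baseline_ages=ages0,
        lateralities=lats,
        config=config,
    )
    return fields, truth
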