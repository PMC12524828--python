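"""Cross-modality archetype comparison.

Cosine similarity (the normalized dot product over the 42-location analysis
vector) is computed for every archetype pair of two fitted models; the dual
mapping then lists, for each archetype of one modality, the most similar
archetype of the other, in both directions.  Threshold tallies summarize how
many best matches reach configured similarity levels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .aa import AAModel
from .grids import GridMismatchError

log = logging.getLogger(__name__)

A_TO_B = "A_to_B"
B_TO_A = "B_to_A"


class ZeroVectorError(ValueError):
    """Cosine similarity is undefined for an all-zero vector."""


def cosine_similarity(u, v) -> float:
    """dot(u, v) / (||u|| ||v||), clipped into [-1, 1].

    Scale-invariant: doubling every entry of either vector leaves the score
    unchanged.  Raises :class:`ZeroVectorError` for a zero vector.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"vectors must share one length; got {u.shape} and {v.shape}")
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("vectors must be finite")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ZeroVectorError("cosine similarity is undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


@dataclass
class SimilarityMatrix:
    values: np.ndarray  # k_A x k_B, NaN where a zero-vector archetype is involved
    row_labels: list
    col_labels: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("similarity matrix shape does not match its labels")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1.0 - 1e-12 or finite.max() > 1.0 + 1e-12):
            raise ValueError("cosine similarities must lie within [-1, 1]")

    @property
    def T(self) -> "SimilarityMatrix":
        return SimilarityMatrix(self.values.T.copy(), list(self.col_labels), list(self.row_labels))


@dataclass
class MappingEntry:
    source: str
    target: str | None       # None when the source archetype is unmapped
    similarity: float | None


@dataclass
class MappingReport:
    direction: str
    entries: list = dc_field(default_factory=list)

    def similarities(self) -> list:
        return [e.similarity for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [e.source for e in self.entries],
                "target": [e.target if e.target is not None else "" for e in self.entries],
                "cosine_similarity": [
                    e.similarity if e.similarity is not None else np.nan for e in self.entries
                ],
            }
        )

    @staticmethod
    def from_frame(frame: pd.DataFrame, direction: str) -> "MappingReport":
        entries = []
        for row in frame.itertuples(index=False):
            sim = float(row.cosine_similarity)
            target = str(row.target) if str(row.target) else None
            entries.append(
                MappingEntry(str(row.source), target, None if np.isnan(sim) else sim)
            )
        return MappingReport(direction, entries)


def similarity_matrix(model_a: AAModel, model_b: AAModel) -> SimilarityMatrix:
    """k_A x k_B cosine similarities between archetype vectors of two models."""
    if model_a.grid_name != model_b.grid_name or model_a.Z.shape[1] != model_b.Z.shape[1]:
        raise GridMismatchError("models must be fitted on the same analysis grid")
    Za, Zb = model_a.Z, model_b.Z
    values = np.full((Za.shape[0], Zb.shape[0]), np.nan)
    norm_a = np.linalg.norm(Za, axis=1)
    norm_b = np.linalg.norm(Zb, axis=1)
    for label, norms, side in ((model_a.labels, norm_a, "A"), (model_b.labels, norm_b, "B")):
        for lab, nz in zip(label, norms):
            if nz == 0.0:
                log.warning("model %s archetype %s is a zero vector; left unmapped", side, lab)
    for i in range(Za.shape[0]):
        for j in range(Zb.shape[0]):
            if norm_a[i] > 0.0 and norm_b[j] > 0.0:
                values[i, j] = cosine_similarity(Za[i], Zb[j])
    return SimilarityMatrix(values, model_a.labels, model_b.labels)


def dual_map(matrix: SimilarityMatrix):
    """Best-match reports in both directions (row argmax and column argmax).

    Many-to-one matches are allowed; exact ties break toward the lower target
    index.  Sources whose row/column is entirely NaN are reported unmapped.
    """
    if matrix.values.size == 0:
        raise ValueError("empty similarity matrix")
    return (
        _argmax_report(matrix, A_TO_B),
        _argmax_report(matrix.T, B_TO_A),
    )


def _argmax_report(matrix: SimilarityMatrix, direction: str) -> MappingReport:
    entries = []
    for i, src in enumerate(matrix.row_labels):
        row = matrix.values[i]
        if np.all(np.isnan(row)):
            entries.append(MappingEntry(src, None, None))
            continue
        j = int(np.nanargmax(row))  # first maximum -> lowest target index on ties
        entries.append(MappingEntry(src, matrix.col_labels[j], float(row[j])))
    return MappingReport(direction, entries)


def threshold_summary(report: MappingReport, thresholds=(0.5, 0.8)) -> dict:
    """Count and fraction of best matches reaching each threshold.

    Unmapped entries count in the denominator but never toward a tally.
    """
    if not report.entries:
        raise ValueError("empty mapping report")
    n = len(report.entries)
    out = {}
    for t in thresholds:
        count = sum(1 for e in report.entries if e.similarity is not None and e.similarity >= t)
        out[float(t)] = {"count": count, "n": n, "fraction": count / n}
    return out


def combined_threshold_summary(reports, thresholds=(0.5, 0.8)) -> dict:
    """Pool entries across both mapping directions before tallying."""
    pooled = MappingReport("combined", [e for r in reports for e in r.entries])
    return threshold_summary(pooled, thresholds)


def summaries_to_json(per_direction: dict, combined: dict) -> str:
    def fix(d):
        return {str(k): v for k, v in d.items()}

    payload = {
        "per_direction": {name: fix(s) for name, s in per_direction.items()},
        "combined": fix(combined),
    }
    return json.dumps(payload, indent=1, sort_keys=True)
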