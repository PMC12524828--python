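"""Reference best-match archetype mapping tables used for tally verification.

Each entry is ``(source archetype, best-match target archetype, cosine
similarity)``.  ``ABSOLUTE_*`` are the reference values for the
absolute-field analysis, ``CHANGE_*`` for the change analysis.  Directions:
``III_TO_SMP`` maps each size III archetype to its most similar SMP
archetype, ``SMP_TO_III`` the reverse.
"""

from __future__ import annotations

from .concordance import A_TO_B, B_TO_A, MappingEntry, MappingReport

ABSOLUTE_III_TO_SMP = (
    ("AT1", "AT3", 0.90),
    ("AT2", "AT5", 0.31),
    ("AT3", "AT5", 0.76),
    ("AT4", "AT4", 0.88),
    ("AT5", "AT10", 0.83),
    ("AT6", "AT6", 0.82),
    ("AT7", "AT9", 0.73),
    ("AT8", "AT5", 0.53),
    ("AT9", "AT3", 0.77),
    ("AT10", "AT10", 0.54),
)

ABSOLUTE_SMP_TO_III = (
    ("AT1", "AT1", 0.56),
    ("AT2", "AT9", 0.63),
    ("AT3", "AT1", 0.90),
    ("AT4", "AT4", 0.88),
    ("AT5", "AT3", 0.76),
    ("AT6", "AT6", 0.82),
    ("AT7", "AT6", 0.76),
    ("AT8", "AT1", 0.71),
    ("AT9", "AT5", 0.76),
    ("AT10", "AT1", 0.84),
)

CHANGE_III_TO_SMP = (
    ("AT1", "AT7", 0.45),
    ("AT2", "AT2", 0.61),
    ("AT3", "AT2", 0.54),
    ("AT4", "AT2", 0.34),
    ("AT5", "AT1", 0.31),
    ("AT6", "AT5", 0.67),
    ("AT7", "AT7", 0.37),
    ("AT8", "AT7", 0.45),
    ("AT9", "AT2", 0.34),
    ("AT10", "AT5", 0.26),
)

CHANGE_SMP_TO_III = (
    ("AT1", "AT7", 0.32),
    ("AT2", "AT2", 0.61),
    ("AT3", "AT6", 0.35),
    ("AT4", "AT4", 0.26),
    ("AT5", "AT6", 0.67),
    ("AT6", "AT3", 0.25),
    ("AT7", "AT6", 0.52),
    ("AT8", "AT2", 0.31),
    ("AT9", "AT1", 0.43),
    ("AT10", "AT7", 0.34),
)


def _report(rows, direction: str) -> MappingReport:
    return MappingReport(direction, [MappingEntry(s, t, v) for s, t, v in rows])


def absolute_mapping_reports() -> tuple[MappingReport, MappingReport]:
    """Absolute-analysis mapping tables as :class:`MappingReport` pairs."""
    return _report(ABSOLUTE_III_TO_SMP, A_TO_B), _report(ABSOLUTE_SMP_TO_III, B_TO_A)


def change_mapping_reports() -> tuple[MappingReport, MappingReport]:
    """Change-analysis mapping tables as :class:`MappingReport` pairs."""
    return _report(CHANGE_III_TO_SMP, A_TO_B), _report(CHANGE_SMP_TO_III, B_TO_A)
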