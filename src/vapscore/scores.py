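"""Deterministic clinical score computation for suspected VAP.

Implements the six-component Clinical Pulmonary Infection Score (CPIS,
0–12) and its biomarker/ultrasound variants:

========== =================================================== =======
score      components                                          range
========== =================================================== =======
cpis       temperature + leukocytes + oxygenation + secretions
           + radiography + microbiology                        0–12
lus        consolidation type + size + laterality + bronchogram 0–9
cpis_lus   cpis without radiography, plus lus                  0–19
cpis_pct   cpis plus procalcitonin points                      0–14
cpis_plus  cpis without radiography, plus procalcitonin points
           and lus                                             0–21
========== =================================================== =======

The ultrasound variants replace the chest-X-ray component with lung
ultrasound findings, following the adult precedents that substituted CXR
for LUS.  Any composite whose input is missing is undefined (``None``),
never imputed.

Band conventions for the continuous CPIS components are half-open so that
every measurement maps to exactly one band: temperature [36.5, 38.5) → 0,
[38.5, 39.0) → 1, ≤ 36.0 or ≥ 39.0 → 2, and the residual gap
(36.0, 36.5) maps to 0 (the clinically normal side).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

from .records import (
    Bronchogram,
    ConsolidationType,
    Laterality,
    LusExam,
    Microbiology,
    PatientRecord,
    Radiography,
    Secretions,
    SizeBand,
    ValidationError,
)

SCORE_NAMES = ("cpis", "lus", "cpis_lus", "cpis_pct", "cpis_plus")

#: Attainable (min, max) range of each score variant.
SCORE_RANGES = {
    "cpis": (0, 12),
    "lus": (0, 9),
    "cpis_lus": (0, 19),
    "cpis_pct": (0, 14),
    "cpis_plus": (0, 21),
}

#: Published point table for the lung-ultrasound findings.
DEFAULT_LUS_TABLE: Mapping[str, Mapping[str, int]] = {
    "consolidation_type": {"none": 0, "subpleural": 1, "lobar": 2},
    "size_band": {"none": 0, "lt15": 0, "s15to20": 1, "gt20": 2},
    "laterality": {"none": 0, "bilateral": 1, "unilateral": 2},
    "bronchogram": {"none": 0, "static": 1, "dynamic": 3},
}


def temperature_points(temperature: float) -> int:
    if not (25.0 <= temperature <= 45.0):
        raise ValidationError(f"temperature {temperature} outside [25, 45]")
    if temperature <= 36.0 or temperature >= 39.0:
        return 2
    if temperature >= 38.5:
        return 1
    return 0


def leukocyte_points(wbc: float, band_forms: float = 0.0) -> int:
    # Band forms only escalate an already abnormal count.
    if wbc < 0 or band_forms < 0:
        raise ValidationError("wbc and band_forms must be non-negative")
    if 4000 <= wbc <= 11000:
        return 0
    return 2 if band_forms >= 500 else 1


def oxygenation_points(pf_ratio: float, ards: bool = False) -> int:
    if not pf_ratio > 0:
        raise ValidationError(f"pf_ratio must be positive, got {pf_ratio}")
    return 0 if (pf_ratio > 240 or ards) else 2


_SECRETIONS_POINTS = {
    Secretions.ABSENT_MINIMAL: 0,
    Secretions.NON_PURULENT: 1,
    Secretions.PURULENT: 2,
}
_RADIOGRAPHY_POINTS = {
    Radiography.NO_INFILTRATE: 0,
    Radiography.PATCHY_DIFFUSE: 1,
    Radiography.LOCALIZED: 2,
}
_MICROBIOLOGY_POINTS = {
    Microbiology.NEGATIVE: 0,
    Microbiology.POSITIVE: 1,
    Microbiology.POSITIVE_WITH_GRAM_MATCH: 2,
}


def cpis_component_points(component: str, measurement, **extra) -> int:
    """Points (0–2) for a single CPIS component.

    Parameters
    ----------
    component : str
        One of ``temperature``, ``leukocytes``, ``oxygenation``,
        ``secretions``, ``radiography``, ``microbiology``.
    measurement :
        Component-specific value (°C, WBC/mm³, PaO₂/FiO₂, or category).
    **extra :
        ``bands=`` band-form count for ``leukocytes``; ``ards=`` flag for
        ``oxygenation``.
    """
    if component == "temperature":
        return temperature_points(measurement)
    if component == "leukocytes":
        return leukocyte_points(measurement, extra.get("bands", 0.0))
    if component == "oxygenation":
        return oxygenation_points(measurement, extra.get("ards", False))
    if component == "secretions":
        return _SECRETIONS_POINTS[Secretions(measurement)]
    if component == "radiography":
        return _RADIOGRAPHY_POINTS[Radiography(measurement)]
    if component == "microbiology":
        return _MICROBIOLOGY_POINTS[Microbiology(measurement)]
    raise ValidationError(f"unknown CPIS component {component!r}")


def pct_points(pct: float) -> int:
    """Procalcitonin points: 0 for < 0.5 ng/mL, 1 for [0.5, 1), 2 for ≥ 1."""
    if pct < 0:
        raise ValidationError(f"pct must be non-negative, got {pct}")
    if pct < 0.5:
        return 0
    if pct < 1.0:
        return 1
    return 2


def lus_points(
    exam: LusExam,
    table: Mapping[str, Mapping[str, int]] = DEFAULT_LUS_TABLE,
) -> tuple[int, dict[str, int]]:
    """Lung-ultrasound sub-score and its per-feature breakdown.

    Returns the sum of the four feature points and a ``feature → points``
    map.  ``table`` may be a derived score table (see
    :mod:`vapscore.derivation`) to score with data-driven points instead of
    the published ones.
    """
    breakdown = {
        "lus_consolidation_type": table["consolidation_type"][exam.consolidation_type.value],
        "lus_size_band": table["size_band"][exam.size_band.value],
        "lus_laterality": table["laterality"][exam.laterality.value],
        "lus_bronchogram": table["bronchogram"][exam.bronchogram.value],
    }
    return sum(breakdown.values()), breakdown


@dataclass
class ScorePanel:
    """The five score variants for one patient.

    Undefined scores are ``None``; each defined composite equals the sum of
    its entries in ``component_breakdown``.
    """

    cpis: Optional[int]
    lus_score: Optional[int]
    cpis_lus: Optional[int]
    cpis_pct: Optional[int]
    cpis_plus: Optional[int]
    component_breakdown: dict[str, Optional[int]] = field(default_factory=dict)

    def get(self, score_name: str) -> Optional[int]:
        key = "lus_score" if score_name == "lus" else score_name
        return getattr(self, key)


def compute_scores(
    patient: PatientRecord,
    lus_table: Mapping[str, Mapping[str, int]] = DEFAULT_LUS_TABLE,
) -> ScorePanel:
    """Compute every score variant defined by the patient's available inputs.

    The CPIS core (temperature, leukocytes, oxygenation, secretions,
    microbiology) is always computable.  Full CPIS additionally needs the
    radiography reading; cpis_pct needs PCT; the ultrasound variants need a
    LUS exam (and PCT for cpis_plus).  Missing inputs propagate to
    ``None``, never to a numeric default.
    """
    breakdown: dict[str, Optional[int]] = {
        "temperature": temperature_points(patient.temperature),
        "leukocytes": leukocyte_points(patient.wbc, patient.band_forms),
        "oxygenation": oxygenation_points(patient.pf_ratio, patient.ards),
        "secretions": _SECRETIONS_POINTS[patient.secretions],
        "microbiology": _MICROBIOLOGY_POINTS[patient.microbiology],
    }
    core = sum(breakdown.values())  # CPIS without the radiography component

    breakdown["radiography"] = (
        _RADIOGRAPHY_POINTS[patient.radiography]
        if patient.radiography is not None
        else None
    )
    breakdown["pct"] = pct_points(patient.pct) if patient.pct is not None else None

    lus_score: Optional[int] = None
    if patient.lus is not None:
        lus_score, lus_breakdown = lus_points(patient.lus, lus_table)
        breakdown.update(lus_breakdown)
    else:
        breakdown.update(
            {k: None for k in (
                "lus_consolidation_type", "lus_size_band",
                "lus_laterality", "lus_bronchogram",
            )}
        )

    cpis = core + breakdown["radiography"] if breakdown["radiography"] is not None else None
    cpis_pct = cpis + breakdown["pct"] if (cpis is not None and breakdown["pct"] is not None) else None
    cpis_lus = core + lus_score if lus_score is not None else None
    cpis_plus = (
        core + breakdown["pct"] + lus_score
        if (breakdown["pct"] is not None and lus_score is not None)
        else None
    )

    return ScorePanel(
        cpis=cpis,
        lus_score=lus_score,
        cpis_lus=cpis_lus,
        cpis_pct=cpis_pct,
        cpis_plus=cpis_plus,
        component_breakdown=breakdown,
    )


class Comparison(str, enum.Enum):
    GE = "ge"
    GT = "gt"


@dataclass(frozen=True)
class ThresholdRule:
    """A positivity rule: score ≥ cutoff (``ge``) or score > cutoff (``gt``)."""

    score_name: str
    cutoff: int
    comparison: Comparison = Comparison.GE

    def __post_init__(self) -> None:
        if self.score_name not in SCORE_NAMES:
            raise ValidationError(
                f"unknown score {self.score_name!r}; expected one of {SCORE_NAMES}"
            )
        lo, hi = SCORE_RANGES[self.score_name]
        if not (lo <= self.cutoff <= hi):
            raise ValidationError(
                f"cutoff {self.cutoff} outside attainable range [{lo}, {hi}] "
                f"of {self.score_name}"
            )
        object.__setattr__(self, "comparison", Comparison(self.comparison))

    @property
    def label(self) -> str:
        op = ">=" if self.comparison == Comparison.GE else ">"
        return f"{self.score_name}{op}{self.cutoff}"


#: The published operating rules for the five variants.
DEFAULT_RULES: tuple[ThresholdRule, ...] = (
    ThresholdRule("cpis", 6, Comparison.GT),
    ThresholdRule("cpis_lus", 12, Comparison.GE),
    ThresholdRule("cpis_plus", 12, Comparison.GE),
    ThresholdRule("lus", 7, Comparison.GE),
    ThresholdRule("cpis_pct", 7, Comparison.GE),
)


def classify(panel_or_value: Union[ScorePanel, Optional[float]], rule: ThresholdRule) -> str:
    """Apply a threshold rule: ``positive`` / ``negative`` / ``undetermined``.

    Accepts either a :class:`ScorePanel` (the rule's score is looked up) or
    a bare score value (``None``/NaN → undetermined).
    """
    value = (
        panel_or_value.get(rule.score_name)
        if isinstance(panel_or_value, ScorePanel)
        else panel_or_value
    )
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "undetermined"
    if rule.comparison == Comparison.GE:
        return "positive" if value >= rule.cutoff else "negative"
    return "positive" if value > rule.cutoff else "negative"


def parse_rules(spec: str) -> list[ThresholdRule]:
    """Parse rules like ``"cpis_plus>=12,cpis>6"`` into ThresholdRule objects."""
    rules = []
    for token in spec.split(","):
        token = token.strip()
        if not token:
            continue
        if ">=" in token:
            name, cut = token.split(">=")
            cmp = Comparison.GE
        elif ">" in token:
            name, cut = token.split(">")
            cmp = Comparison.GT
        else:
            raise ValidationError(
                f"cannot parse rule {token!r}; expected 'name>=cutoff' or 'name>cutoff'"
            )
        rules.append(ThresholdRule(name.strip(), int(cut), cmp))
    if not rules:
        raise ValidationError(f"no rules found in {spec!r}")
    return rules
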