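"""Patient-level domain types for suspected-VAP episodes.

A cohort is a list of :class:`PatientRecord` objects, one per suspected
ventilator-associated-pneumonia (VAP) episode.  Each record carries the six
CPIS inputs (temperature, leukocytes, oxygenation, secretions, chest
radiography, tracheal-aspirate microbiology), the serum procalcitonin value,
an optional lung-ultrasound exam, and the adjudicated VAP label.  Missing
inputs stay missing (``None``): downstream scores that need them become
undefined rather than imputed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Secretions(str, enum.Enum):
    """Tracheal-secretion category (CPIS component)."""

    ABSENT_MINIMAL = "absent_minimal"
    NON_PURULENT = "non_purulent"
    PURULENT = "purulent"


class Radiography(str, enum.Enum):
    """Chest X-ray infiltrate category (CPIS component)."""

    NO_INFILTRATE = "no_infiltrate"
    PATCHY_DIFFUSE = "patchy_diffuse"
    LOCALIZED = "localized"


class Microbiology(str, enum.Enum):
    """Tracheal-aspirate culture/microscopy result (CPIS component).

    ``POSITIVE_WITH_GRAM_MATCH`` means a positive culture plus the same
    pathogen seen on direct Gram stain of the aspirate.
    """

    NEGATIVE = "negative"
    POSITIVE = "positive"
    POSITIVE_WITH_GRAM_MATCH = "positive_with_gram_match"


class ConsolidationType(str, enum.Enum):
    NONE = "none"
    SUBPLEURAL = "subpleural"
    LOBAR = "lobar"


class SizeBand(str, enum.Enum):
    """Consolidation diameter band in millimetres."""

    NONE = "none"
    LT15 = "lt15"
    S15TO20 = "s15to20"
    GT20 = "gt20"


class Laterality(str, enum.Enum):
    NONE = "none"
    BILATERAL = "bilateral"
    UNILATERAL = "unilateral"


class Bronchogram(str, enum.Enum):
    """Air bronchogram within a consolidation; dynamic means the air-filled
    bronchi visibly move with respiration."""

    NONE = "none"
    STATIC = "static"
    DYNAMIC = "dynamic"


class ValidationError(ValueError):
    """Raised when a record or exam violates its domain invariants."""


def size_band_from_mm(size_mm: float) -> SizeBand:
    """Map a numeric consolidation diameter to its band.

    Boundaries are <15 / [15, 20] / >20 mm; exactly 20.0 mm falls in the
    middle band.
    """
    if size_mm < 15:
        return SizeBand.LT15
    if size_mm <= 20:
        return SizeBand.S15TO20
    return SizeBand.GT20


@dataclass(frozen=True)
class LusExam:
    """Categorical lung-ultrasound findings for one exam.

    Invariant: without a consolidation there is no size or laterality.  A
    bronchogram only makes sense inside a consolidation, so it is likewise
    forced to ``none`` when no consolidation is present.
    """

    consolidation_type: ConsolidationType
    size_band: SizeBand
    laterality: Laterality
    bronchogram: Bronchogram

    def __post_init__(self) -> None:
        if self.consolidation_type == ConsolidationType.NONE:
            if self.size_band != SizeBand.NONE:
                raise ValidationError(
                    "size_band must be 'none' when there is no consolidation, "
                    f"got {self.size_band.value!r}"
                )
            if self.laterality != Laterality.NONE:
                raise ValidationError(
                    "laterality must be 'none' when there is no consolidation, "
                    f"got {self.laterality.value!r}"
                )
            if self.bronchogram != Bronchogram.NONE:
                raise ValidationError(
                    "bronchogram must be 'none' when there is no consolidation, "
                    f"got {self.bronchogram.value!r}"
                )


@dataclass
class PatientRecord:
    """One suspected-VAP episode.

    Parameters
    ----------
    patient_id : str
        Opaque identifier.
    vap_confirmed : bool
        Final adjudicated VAP diagnosis (consumed as a label).
    temperature : float
        Core temperature, °C.  Must lie in [25, 45].
    wbc : float
        Blood leukocytes per mm³.
    pf_ratio : float
        PaO₂/FiO₂ (dimensionless), > 0.
    ards : bool
        Acute respiratory distress syndrome present.
    secretions : Secretions
    microbiology : Microbiology
    band_forms : float, default 0
        Immature neutrophil (band form) count per mm³.
    radiography : Radiography or None
        Missing when no readable chest X-ray is available.
    pct : float or None
        Procalcitonin, ng/mL; ``None`` when not measured.
    lus : LusExam or None
        ``None`` when no lung ultrasound was performed.
    """

    patient_id: str
    vap_confirmed: bool
    temperature: float
    wbc: float
    pf_ratio: float
    ards: bool
    secretions: Secretions
    microbiology: Microbiology
    band_forms: float = 0.0
    radiography: Optional[Radiography] = None
    pct: Optional[float] = None
    lus: Optional[LusExam] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (25.0 <= self.temperature <= 45.0):
            raise ValidationError(
                f"temperature {self.temperature} °C outside plausible range [25, 45]"
            )
        if self.wbc < 0:
            raise ValidationError(f"wbc must be non-negative, got {self.wbc}")
        if self.band_forms < 0:
            raise ValidationError(
                f"band_forms must be non-negative, got {self.band_forms}"
            )
        if not self.pf_ratio > 0:
            raise ValidationError(f"pf_ratio must be positive, got {self.pf_ratio}")
        if self.pct is not None and self.pct < 0:
            raise ValidationError(f"pct must be non-negative, got {self.pct}")
        self.secretions = Secretions(self.secretions)
        self.microbiology = Microbiology(self.microbiology)
        if self.radiography is not None:
            self.radiography = Radiography(self.radiography)
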