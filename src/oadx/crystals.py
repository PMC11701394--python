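"""Compensated polarized-light microscopy decision table and prevalence.

Monosodium urate (MSU, gout) and calcium pyrophosphate dihydrate (CPPD,
"pseudogout") crystals are distinguished by morphology, birefringence
strength, and the colors seen parallel/perpendicular to the compensator
axis:

====================  ==============  ============  ==========  =============
crystal               shape           birefringence parallel    perpendicular
====================  ==============  ============  ==========  =============
MSU (gout)            needle          high          yellow      blue
CPPD (CPPD disease)   rhombic/square  weak          blue        yellow
cholesterol           plate/other     (any)         (any)       (any)
====================  ==============  ============  ==========  =============

A partially matching feature combination is *indeterminate*, never
silently coerced to the nearest class.  Intracellular vs. extracellular
location is recorded but does not change the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .errors import DomainError
from .model import Diagnosis, Specimen, _round_half_up

__all__ = [
    "Shape",
    "Birefringence",
    "CompensatedColor",
    "Location",
    "CrystalType",
    "Disorder",
    "CrystalObservation",
    "CrystalCall",
    "classify_crystal",
    "crystal_prevalence",
    "CrystalPrevalence",
]


class Shape(str, Enum):
    NEEDLE = "needle"
    RHOMBIC_SQUARE = "rhombic_square"
    PLATE_OTHER = "plate_other"


class Birefringence(str, Enum):
    HIGH = "high"
    WEAK = "weak"
    NONE = "none"


class CompensatedColor(str, Enum):
    YELLOW = "yellow"
    BLUE = "blue"
    NONE = "none"


class Location(str, Enum):
    INTRACELLULAR = "intracellular"
    EXTRACELLULAR = "extracellular"


class CrystalType(str, Enum):
    MSU = "MSU"
    CPPD = "CPPD"
    CHOLESTEROL = "cholesterol"
    NONE = "none"
    INDETERMINATE = "indeterminate"


class Disorder(str, Enum):
    GOUT = "gout"
    CPPD_DISEASE = "CPPD_disease"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class CrystalObservation:
    """One coded microscopy finding for a specimen."""

    shape: Shape
    birefringence: Birefringence
    parallel_color: CompensatedColor
    perpendicular_color: CompensatedColor
    location: Optional[Location] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", Shape(self.shape))
        object.__setattr__(self, "birefringence", Birefringence(self.birefringence))
        object.__setattr__(self, "parallel_color", CompensatedColor(self.parallel_color))
        object.__setattr__(
            self, "perpendicular_color", CompensatedColor(self.perpendicular_color)
        )
        if self.location is not None:
            object.__setattr__(self, "location", Location(self.location))
        if self.birefringence is Birefringence.NONE and (
            self.parallel_color is not CompensatedColor.NONE
            or self.perpendicular_color is not CompensatedColor.NONE
        ):
            raise DomainError(
                "a non-birefringent body cannot show compensated colors"
            )


@dataclass(frozen=True)
class CrystalCall:
    crystal: CrystalType
    disorder: Disorder

    def __post_init__(self) -> None:
        expected = {
            CrystalType.MSU: Disorder.GOUT,
            CrystalType.CPPD: Disorder.CPPD_DISEASE,
        }.get(self.crystal, Disorder.NOT_APPLICABLE)
        if self.disorder is not expected:
            raise DomainError(
                f"{self.crystal.value} implies disorder {expected.value}, "
                f"got {self.disorder.value}"
            )


def classify_crystal(obs: CrystalObservation) -> CrystalCall:
    """Map one observation to a crystal class and associated disorder.

    The decision table is total: every valid observation maps to exactly
    one of MSU, CPPD, cholesterol, none, or indeterminate.
    """
    if not isinstance(obs, CrystalObservation):
        obs = CrystalObservation(**obs) if isinstance(obs, dict) else obs
    if (
        obs.shape is Shape.NEEDLE
        and obs.birefringence is Birefringence.HIGH
        and obs.parallel_color is CompensatedColor.YELLOW
        and obs.perpendicular_color is CompensatedColor.BLUE
    ):
        return CrystalCall(CrystalType.MSU, Disorder.GOUT)
    if (
        obs.shape is Shape.RHOMBIC_SQUARE
        and obs.birefringence is Birefringence.WEAK
        and obs.parallel_color is CompensatedColor.BLUE
        and obs.perpendicular_color is CompensatedColor.YELLOW
    ):
        return CrystalCall(CrystalType.CPPD, Disorder.CPPD_DISEASE)
    if obs.shape is Shape.PLATE_OTHER:
        return CrystalCall(CrystalType.CHOLESTEROL, Disorder.NOT_APPLICABLE)
    if obs.birefringence is Birefringence.NONE:
        return CrystalCall(CrystalType.NONE, Disorder.NOT_APPLICABLE)
    return CrystalCall(CrystalType.INDETERMINATE, Disorder.NOT_APPLICABLE)


@dataclass(frozen=True)
class CrystalPrevalence:
    """Crystal counts over the examined specimens.

    ``positive`` counts specimens carrying MSU and/or CPPD crystals once
    each, regardless of how many crystal classes they show; cholesterol
    does not contribute to positivity.  ``by_type`` counts a specimen
    once per crystal class present, so type counts can exceed
    ``positive`` when mixed findings occur.
    """

    n_total: int
    n_examined: int
    by_type: dict  # CrystalType -> count of specimens showing that class
    by_cohort: dict  # Diagnosis -> count of crystal-positive specimens
    positive: int

    @property
    def percent_positive(self) -> float:
        if self.n_examined == 0:
            return 0.0
        return _round_half_up(100.0 * self.positive / self.n_examined, 1)


def crystal_prevalence(specimens: Sequence[Specimen]) -> CrystalPrevalence:
    """Tabulate crystal findings by class and cohort.

    Specimens whose ``crystals`` field is ``None`` were not examined and
    are excluded from the denominator; an empty list is a negative
    examination.  Percentages are over examined specimens.
    """
    by_type: dict = {t: 0 for t in CrystalType if t is not CrystalType.NONE}
    by_cohort: dict = {}
    n_examined = 0
    positive = 0
    for s in specimens:
        if s.crystals is None:
            continue
        n_examined += 1
        types = {classify_crystal(o).crystal for o in s.crystals}
        types.discard(CrystalType.NONE)
        for t in types:
            by_type[t] += 1
        if types & {CrystalType.MSU, CrystalType.CPPD}:
            positive += 1
            by_cohort[s.diagnosis] = by_cohort.get(s.diagnosis, 0) + 1
    return CrystalPrevalence(
        n_total=len(specimens),
        n_examined=n_examined,
        by_type=by_type,
        by_cohort=by_cohort,
        positive=positive,
    )
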