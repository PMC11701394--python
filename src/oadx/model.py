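"""Domain types and the two-step COMP / IL-8 osteoarthritis decision rule.

The classifier calls a synovial-fluid specimen *primary-OA positive* when
two gates pass in sequence:

1. **COMP gate** — the cartilage oligomeric matrix protein concentration
   must lie strictly above a clinical decision limit (1500 ng/mL in the
   validation study).  COMP below the limit indicates no measurable
   cartilage deterioration, so the specimen is negative and no ratio is
   computed.
2. **Ratio gate** — the COMP/IL-8 ratio (ng/mL over pg/mL, taken on the
   reported numeric scales without unit conversion) must lie strictly
   above a second decision limit.  A high COMP with a low ratio means
   cartilage breakdown in a highly inflamed joint, i.e. potential
   *secondary* OA, and the specimen is negative.

Both comparisons are strict: a value exactly equal to a limit is "not
above" it and classifies negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .errors import DomainError, SpecimenValidationError

__all__ = [
    "Diagnosis",
    "CensorFlag",
    "Sex",
    "ReasonCode",
    "Specimen",
    "DecisionLimits",
    "ClassificationResult",
    "PositivitySummary",
    "compute_ratio",
    "classify_specimen",
    "classify_cohort",
]


class Diagnosis(str, Enum):
    """Clinical cohort label attached to a specimen."""

    OA = "OA"  # primary osteoarthritis (condition positive)
    RA = "RA"  # rheumatoid arthritis
    CA = "CA"  # crystalline arthritis (gout / CPPD disease)
    NSA = "NSA"  # native septic arthritis
    UNKNOWN = "UNKNOWN"


#: cohorts pooled into the condition-negative "inflammatory arthritis" class
INFLAMMATORY = frozenset({Diagnosis.RA, Diagnosis.CA, Diagnosis.NSA})


class CensorFlag(str, Enum):
    """Whether a reported concentration sits at an assay quantitation limit."""

    NONE = "none"
    AT_LOWER_LIMIT = "at_lower_limit"
    AT_UPPER_LIMIT = "at_upper_limit"


class Sex(str, Enum):
    M = "M"
    F = "F"


class ReasonCode(str, Enum):
    """Why a specimen received its call."""

    PRIMARY_OA_POSITIVE = "primary_oa_positive"
    BELOW_COMP_LIMIT = "below_comp_limit"  # no measurable cartilage loss
    LOW_RATIO = "low_ratio"  # inflamed joint: potential secondary OA


@dataclass(frozen=True)
class DecisionLimits:
    """The two clinical decision limits driving classification.

    Parameters
    ----------
    comp_limit:
        COMP concentration gate in ng/mL (1500 in the validation study).
    ratio_limit:
        COMP/IL-8 ratio gate (ng/mL over pg/mL by convention).  No
        default is provided: the validated value is proprietary and has
        never been published, so callers must supply their own.
    """

    comp_limit: float
    ratio_limit: float

    def __post_init__(self) -> None:
        for name in ("comp_limit", "ratio_limit"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise DomainError(f"{name} must be finite and > 0, got {v!r}")


@dataclass
class Specimen:
    """One knee synovial-fluid record.

    ``comp`` is in ng/mL, ``il8`` in pg/mL.  Censor flags record values
    reported at assay quantitation limits; censored values are used
    as-is in the ratio (the flags are carried for transparency only).
    ``crystals`` is ``None`` when microscopy was not performed and an
    (possibly empty) list of observations when it was.
    """

    id: str
    comp: float
    il8: float
    diagnosis: Diagnosis = Diagnosis.UNKNOWN
    comp_censor: CensorFlag = CensorFlag.NONE
    il8_censor: CensorFlag = CensorFlag.NONE
    kl_grade: Optional[int] = None
    sex: Optional[Sex] = None
    age: Optional[float] = None
    crystals: Optional[list] = None  # list[CrystalObservation]

    def __post_init__(self) -> None:
        self.diagnosis = Diagnosis(self.diagnosis)
        self.comp_censor = CensorFlag(self.comp_censor)
        self.il8_censor = CensorFlag(self.il8_censor)
        if self.sex is not None:
            self.sex = Sex(self.sex)
        for name in ("comp", "il8"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise SpecimenValidationError(
                    f"specimen {self.id!r}: missing {name} value"
                )
            if v < 0:
                raise SpecimenValidationError(
                    f"specimen {self.id!r}: {name} must be >= 0, got {v}"
                )
        if self.kl_grade is not None:
            if int(self.kl_grade) not in (2, 3, 4):
                raise SpecimenValidationError(
                    f"specimen {self.id!r}: KL grade must be 2, 3 or 4, "
                    f"got {self.kl_grade}"
                )
            self.kl_grade = int(self.kl_grade)
            if self.diagnosis is not Diagnosis.OA:
                # KL grading was only performed on the OA cohort
                warnings.warn(
                    f"specimen {self.id!r}: KL grade present but diagnosis "
                    f"is {self.diagnosis.value}",
                    stacklevel=2,
                )

    @property
    def condition_positive(self) -> bool:
        """True when the clinical diagnosis is primary OA."""
        return self.diagnosis is Diagnosis.OA


@dataclass(frozen=True)
class ClassificationResult:
    """Call plus reason code and, when the COMP gate passed, the ratio."""

    call: str  # "positive" | "negative"
    reason: ReasonCode
    ratio: Optional[float] = None

    def __post_init__(self) -> None:
        positive = self.reason is ReasonCode.PRIMARY_OA_POSITIVE
        if (self.call == "positive") != positive:
            raise DomainError(
                f"inconsistent result: call={self.call!r} reason={self.reason}"
            )
        if self.reason is ReasonCode.BELOW_COMP_LIMIT:
            if self.ratio is not None:
                raise DomainError("no ratio is defined below the COMP gate")
        elif self.ratio is None:
            raise DomainError(f"ratio required for reason {self.reason}")

    @property
    def is_positive(self) -> bool:
        return self.call == "positive"


@dataclass(frozen=True)
class PositivitySummary:
    """Cohort-level positivity: count and percent (one decimal)."""

    n: int
    positives: int
    percent: float


def compute_ratio(comp: float, il8: float) -> float:
    """COMP/IL-8 ratio on the reported numeric scales (ng/mL over pg/mL).

    No unit conversion is applied; the composite score is the plain
    quotient of the two reported concentrations.

    Raises
    ------
    DomainError
        If ``il8`` is zero/negative or ``comp`` is negative.
    """
    if comp is None or (isinstance(comp, float) and math.isnan(comp)):
        raise DomainError("comp is missing")
    if il8 is None or (isinstance(il8, float) and math.isnan(il8)):
        raise DomainError("il8 is missing")
    if comp < 0:
        raise DomainError(f"comp must be >= 0, got {comp}")
    if il8 <= 0:
        raise DomainError(f"il8 must be > 0 to form a ratio, got {il8}")
    return comp / il8


def classify_specimen(s: Specimen, limits: DecisionLimits) -> ClassificationResult:
    """Apply the two-step decision rule to one specimen.

    Gate order matters: when COMP is at or below ``comp_limit`` the
    specimen is negative with reason ``below_comp_limit`` and no ratio is
    computed (mirroring clinical practice, where the reflex IL-8 test is
    not needed).  Otherwise the ratio decides.
    """
    if not math.isfinite(s.comp):
        raise SpecimenValidationError(f"specimen {s.id!r}: non-finite comp")
    if s.comp <= limits.comp_limit:
        return ClassificationResult("negative", ReasonCode.BELOW_COMP_LIMIT)
    try:
        ratio = compute_ratio(s.comp, s.il8)
    except DomainError as exc:
        raise DomainError(f"specimen {s.id!r}: {exc}") from exc
    if ratio > limits.ratio_limit:
        return ClassificationResult("positive", ReasonCode.PRIMARY_OA_POSITIVE, ratio)
    return ClassificationResult("negative", ReasonCode.LOW_RATIO, ratio)


def classify_cohort(
    specimens: Sequence[Specimen], limits: DecisionLimits
) -> tuple[list[ClassificationResult], PositivitySummary]:
    """Classify every specimen and summarise positivity.

    Returns the element-wise results (input order preserved) and a
    :class:`PositivitySummary` whose percent is reported to one decimal.
    """
    specimens = list(specimens)
    if not specimens:
        raise DomainError("classify_cohort requires a non-empty specimen list")
    results = [classify_specimen(s, limits) for s in specimens]
    pos = sum(r.is_positive for r in results)
    pct = _round_half_up(100.0 * pos / len(specimens), 1)
    return results, PositivitySummary(len(specimens), pos, pct)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), matching clinical reporting."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
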