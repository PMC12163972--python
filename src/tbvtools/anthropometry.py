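"""Anthropometric primitives: BMI, Devine ideal body weight, adjusted IBW,
and obesity classification.

These are the inputs every total-blood-volume formula consumes.  Obesity is
BMI >= 30; the analysis merges severe (35.0-39.9) and morbid (>= 40) obesity
into a single "severe" class because morbidly obese subjects are sparse in
typical apheresis cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import ValidationError

__all__ = [
    "Sex",
    "ObesityClass",
    "PatientRecord",
    "AnthropometricProfile",
    "compute_bmi",
    "devine_ibw",
    "adjusted_ibw",
    "classify_obesity",
    "profile_for",
]

HEIGHT_BOUNDS_CM = (100.0, 250.0)
HCT_BOUNDS = (0.10, 0.65)

# Devine (1974) intercepts, kg; slope 0.91 kg per cm above 152.4 cm (5 ft)
_DEVINE_INTERCEPT = {"male": 50.0, "female": 45.5}
_DEVINE_SLOPE = 0.91
_DEVINE_REFERENCE_CM = 152.4

# AIBW = IBW + 0.25 * (ABW - IBW): a fixed convex combination placing a
# quarter of the excess weight back onto the ideal weight.
_AIBW_EXCESS_FRACTION = 0.25


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, token: str) -> "Sex":
        """Accept case-insensitive {male, female, M, F}."""
        t = str(token).strip().lower()
        if t in ("male", "m"):
            return cls.MALE
        if t in ("female", "f"):
            return cls.FEMALE
        raise ValidationError("sex", f"unknown sex token {token!r}")


class ObesityClass(str, Enum):
    NON_OBESE = "non_obese"
    NON_SEVERE = "non_severe"  # BMI 30.0-34.9
    SEVERE = "severe"          # BMI >= 35.0 (morbid merged in)

    @property
    def rank(self) -> int:
        return {"non_obese": 0, "non_severe": 1, "severe": 2}[self.value]


def compute_bmi(height_cm: float, weight_kg: float) -> float:
    """Body mass index, kg/m^2, at full precision (no rounding)."""
    _check_height(height_cm)
    _check_weight(weight_kg)
    return weight_kg / (height_cm / 100.0) ** 2


def devine_ibw(sex: Sex | str, height_cm: float) -> float:
    """Devine ideal body weight, kg: intercept + 0.91*(height_cm - 152.4).

    The intercept is 50 kg for men and 45.5 kg for women.  Heights below the
    152.4 cm reference extrapolate linearly downward, as in common clinical
    usage.
    """
    _check_height(height_cm)
    sex = Sex(sex) if not isinstance(sex, Sex) else sex
    intercept = _DEVINE_INTERCEPT[sex.value]
    return intercept + _DEVINE_SLOPE * (height_cm - _DEVINE_REFERENCE_CM)


def adjusted_ibw(ibw_kg: float, abw_kg: float) -> float:
    """Adjusted ideal body weight: IBW + 0.25*(ABW - IBW)."""
    if ibw_kg <= 0:
        raise ValidationError("ibw_kg", "must be positive")
    if abw_kg <= 0:
        raise ValidationError("abw_kg", "must be positive")
    return ibw_kg + _AIBW_EXCESS_FRACTION * (abw_kg - ibw_kg)


def classify_obesity(bmi: float) -> ObesityClass:
    """Classify BMI: < 30 non-obese, [30, 35) non-severe, >= 35 severe."""
    if bmi <= 0:
        raise ValidationError("bmi", "must be positive")
    if bmi < 30.0:
        return ObesityClass.NON_OBESE
    if bmi < 35.0:
        return ObesityClass.NON_SEVERE
    return ObesityClass.SEVERE


@dataclass(frozen=True)
class PatientRecord:
    """One subject: sex, height, actual body weight and hematocrit."""

    id: str
    sex: Sex
    height_cm: float
    weight_kg: float
    hematocrit: float = 0.40

    def __post_init__(self):
        object.__setattr__(self, "sex", Sex(self.sex))
        _check_height(self.height_cm)
        _check_weight(self.weight_kg)
        lo, hi = HCT_BOUNDS
        if not (lo < self.hematocrit < hi):
            raise ValidationError(
                "hematocrit", f"{self.hematocrit} outside ({lo}, {hi})"
            )


@dataclass(frozen=True)
class AnthropometricProfile:
    """Derived anthropometrics for one patient."""

    bmi: float
    ibw_kg: float
    aibw_kg: float
    obesity_class: ObesityClass = field(default=ObesityClass.NON_OBESE)


def profile_for(record: PatientRecord) -> AnthropometricProfile:
    """Compute the full anthropometric profile for a patient record."""
    bmi = compute_bmi(record.height_cm, record.weight_kg)
    ibw = devine_ibw(record.sex, record.height_cm)
    aibw = adjusted_ibw(ibw, record.weight_kg)
    return AnthropometricProfile(
        bmi=bmi, ibw_kg=ibw, aibw_kg=aibw, obesity_class=classify_obesity(bmi)
    )


def _check_height(height_cm: float) -> None:
    lo, hi = HEIGHT_BOUNDS_CM
    if not (lo < height_cm < hi):
        raise ValidationError("height_cm", f"{height_cm} outside ({lo}, {hi})")


def _check_weight(weight_kg: float) -> None:
    if not weight_kg > 0:
        raise ValidationError("weight_kg", f"{weight_kg} must be positive")
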