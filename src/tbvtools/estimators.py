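"""The total-blood-volume formula registry.

Three estimator families are implemented, each with the weight basis used in
apheresis practice for obese patients:

* Nadler's regression (1962, isotope-dilution data): cubic in height plus
  linear in weight, sex-specific constants; evaluated here on the adjusted
  ideal body weight (AIBW).
* Lemmens-Bernstein (2006, developed for obese subjects):
  ``70 mL/kg * ABW / sqrt(BMI/22)``, always on actual body weight, with the
  BMI computed at full precision from the raw height and weight.
* Gilcher's rule of fives: weight times a population-average constant
  (60 mL/kg for obese men, 55 mL/kg for obese women), on either ABW or AIBW.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

from .anthropometry import AnthropometricProfile, PatientRecord, Sex, compute_bmi
from .errors import ConfigurationError, ValidationError

__all__ = [
    "FormulaId",
    "WeightBasis",
    "TbvEstimate",
    "EstimateSet",
    "EstimateKey",
    "nadler",
    "lemmens_bernstein",
    "gilcher",
    "estimate_all",
    "DEFAULT_FORMULA_MATRIX",
    "resolve_formula",
]


class FormulaId(str, Enum):
    NADLER_MALE = "nadler_male"
    NADLER_FEMALE = "nadler_female"
    LEMMENS_BERNSTEIN = "lemmens_bernstein"
    GILCHER_60 = "gilcher_60"
    GILCHER_55 = "gilcher_55"


class WeightBasis(str, Enum):
    ABW = "abw"
    AIBW = "aibw"


EstimateKey = tuple[FormulaId, WeightBasis]

# intercept (mL), height coefficient (mL/cm^3), weight coefficient (mL/kg)
_NADLER = {
    Sex.MALE: (604.1, 0.0003668, 32.0),
    Sex.FEMALE: (183.3, 0.000356, 33.0),
}

GILCHER_CONSTANTS = {FormulaId.GILCHER_60: 60.0, FormulaId.GILCHER_55: 55.0}

_LB_REFERENCE_BMI = 22.0
_LB_ML_PER_KG = 70.0

# The formula/basis matrix applied per patient by default: Nadler on AIBW,
# Lemmens-Bernstein on ABW, Gilcher on both ABW and AIBW.  Generic names are
# resolved to the sex-specific variant at evaluation time.
DEFAULT_FORMULA_MATRIX: tuple[tuple[str, WeightBasis], ...] = (
    ("nadler", WeightBasis.AIBW),
    ("lemmens_bernstein", WeightBasis.ABW),
    ("gilcher", WeightBasis.ABW),
    ("gilcher", WeightBasis.AIBW),
)


def nadler(sex: Sex | str, height_cm: float, weight_kg: float) -> float:
    """Nadler's formula, mL, on whatever weight basis the caller supplies."""
    sex = Sex(sex) if not isinstance(sex, Sex) else sex
    if not (100.0 < height_cm < 250.0):
        raise ValidationError("height_cm", f"{height_cm} outside (100, 250)")
    if weight_kg <= 0:
        raise ValidationError("weight_kg", "must be positive")
    intercept, h_coef, w_coef = _NADLER[sex]
    return intercept + h_coef * height_cm**3 + w_coef * weight_kg


def lemmens_bernstein(height_cm: float, weight_kg_abw: float) -> float:
    """Lemmens-Bernstein formula, mL: 70*ABW / sqrt(BMI/22).

    The BMI is recomputed internally from the raw height and actual weight so
    that weight and BMI are always self-consistent and unrounded.
    """
    bmi = compute_bmi(height_cm, weight_kg_abw)
    return _LB_ML_PER_KG * weight_kg_abw / math.sqrt(bmi / _LB_REFERENCE_BMI)


def gilcher(weight_kg: float, constant_mL_per_kg: float) -> float:
    """Gilcher's rule of fives: weight times a population-average constant."""
    if weight_kg <= 0:
        raise ValidationError("weight_kg", "must be positive")
    if constant_mL_per_kg <= 0:
        raise ValidationError("constant_mL_per_kg", "must be positive")
    return weight_kg * constant_mL_per_kg


@dataclass(frozen=True)
class TbvEstimate:
    """One formula's TBV output for one patient."""

    formula_id: FormulaId
    weight_basis: WeightBasis
    weight_used_kg: float
    tbv_mL: float

    @property
    def key(self) -> EstimateKey:
        return (self.formula_id, self.weight_basis)

    @property
    def label(self) -> str:
        return f"{self.formula_id.value}/{self.weight_basis.value}"


@dataclass
class EstimateSet:
    """All configured formula estimates for one patient."""

    patient_id: str
    sex: Sex
    bmi: float
    estimates: dict[EstimateKey, TbvEstimate] = field(default_factory=dict)

    def add(self, estimate: TbvEstimate) -> None:
        if estimate.key in self.estimates:
            raise ConfigurationError(
                f"duplicate estimate {estimate.label} for patient {self.patient_id}"
            )
        self.estimates[estimate.key] = estimate

    def get(self, formula_id: FormulaId, basis: WeightBasis) -> TbvEstimate:
        return self.estimates[(formula_id, basis)]

    def tbv(self, formula_id: FormulaId, basis: WeightBasis) -> float:
        return self.estimates[(formula_id, basis)].tbv_mL

    def __len__(self) -> int:
        return len(self.estimates)

    def __contains__(self, key: EstimateKey) -> bool:
        return key in self.estimates


def resolve_formula(name: str, sex: Sex) -> FormulaId:
    """Map a generic formula name to the sex-specific registry variant.

    Explicit variant ids (e.g. ``nadler_female``) pass through unchanged so a
    configuration can override the sex matching.
    """
    n = name.strip().lower()
    if n == "nadler":
        return FormulaId.NADLER_MALE if sex is Sex.MALE else FormulaId.NADLER_FEMALE
    if n == "gilcher":
        return FormulaId.GILCHER_60 if sex is Sex.MALE else FormulaId.GILCHER_55
    try:
        return FormulaId(n)
    except ValueError:
        raise ConfigurationError(f"unknown formula id {name!r}") from None


def _evaluate(
    formula_id: FormulaId,
    basis: WeightBasis,
    patient: PatientRecord,
    profile: AnthropometricProfile,
    gilcher_constants: Mapping[FormulaId, float],
) -> TbvEstimate:
    weight = patient.weight_kg if basis is WeightBasis.ABW else profile.aibw_kg
    if formula_id in (FormulaId.NADLER_MALE, FormulaId.NADLER_FEMALE):
        sex = Sex.MALE if formula_id is FormulaId.NADLER_MALE else Sex.FEMALE
        tbv = nadler(sex, patient.height_cm, weight)
    elif formula_id is FormulaId.LEMMENS_BERNSTEIN:
        if basis is not WeightBasis.ABW:
            raise ConfigurationError(
                "lemmens_bernstein requires the ABW basis: its internal BMI "
                "and weight must refer to the same body weight"
            )
        tbv = lemmens_bernstein(patient.height_cm, patient.weight_kg)
    elif formula_id in (FormulaId.GILCHER_60, FormulaId.GILCHER_55):
        tbv = gilcher(weight, gilcher_constants[formula_id])
    else:  # pragma: no cover - enum is closed
        raise ConfigurationError(f"unknown formula id {formula_id!r}")
    return TbvEstimate(
        formula_id=formula_id, weight_basis=basis, weight_used_kg=weight, tbv_mL=tbv
    )


def estimate_all(
    patient: PatientRecord,
    profile: AnthropometricProfile,
    formula_matrix: Iterable[tuple[str, WeightBasis]] = DEFAULT_FORMULA_MATRIX,
    gilcher_constants: Optional[Mapping[FormulaId, float]] = None,
) -> EstimateSet:
    """Apply the configured (formula, weight basis) matrix to one patient.

    Generic names in the matrix are resolved by the patient's sex; an empty
    matrix yields an empty estimate set.
    """
    constants = dict(GILCHER_CONSTANTS)
    if gilcher_constants:
        constants.update(gilcher_constants)
    out = EstimateSet(patient_id=patient.id, sex=patient.sex, bmi=profile.bmi)
    for name, basis in formula_matrix:
        basis = WeightBasis(basis)
        formula_id = resolve_formula(name, patient.sex)
        out.add(_evaluate(formula_id, basis, patient, profile, constants))
    return out
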