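"""Seeded synthetic cohort generator.

Builds cohorts with the statistical structure the comparison pipeline
assumes: a fixed number of obese women and men (58 / 97 by default), heights
drawn per sex from a truncated normal, and BMI drawn from a shifted Gamma so
that every subject is obese (BMI >= 30), the spectrum is right-skewed
reaching past 40, and roughly 59% of subjects fall in the non-severe class
(BMI 30.0-34.9).  Weight is derived as BMI * height^2, so height, weight and
BMI are self-consistent by construction.

``inject_class_shift`` adds a known weight offset to severe-class subjects
so the severity-group comparison has a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammainc

from .anthropometry import ObesityClass, PatientRecord, Sex, classify_obesity, compute_bmi
from .errors import ConfigurationError, ValidationError
from .estimators import FormulaId, GILCHER_CONSTANTS, WeightBasis

__all__ = [
    "SyntheticCohortConfig",
    "ClassShiftResult",
    "generate",
    "expected_nonsevere_fraction",
    "inject_class_shift",
]

# Nadler weight coefficients, mL per kg, used to size weight shifts
_NADLER_SLOPE = {FormulaId.NADLER_MALE: 32.0, FormulaId.NADLER_FEMALE: 33.0}
# dAIBW/dABW: a weight shift on the AIBW basis needs 4x the ABW change
_AIBW_DERIVATIVE = 0.25


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generator settings; defaults emulate a 155-subject obese apheresis cohort."""

    n_female: int = 58
    n_male: int = 97
    seed: int = 0
    height_mean_cm: dict = field(
        default_factory=lambda: {Sex.FEMALE: 163.0, Sex.MALE: 177.0}
    )
    height_sd_cm: dict = field(
        default_factory=lambda: {Sex.FEMALE: 6.5, Sex.MALE: 7.0}
    )
    height_bounds_cm: tuple[float, float] = (145.0, 200.0)
    # BMI = offset + Gamma(shape, scale), truncated at bmi_max
    bmi_offset: float = 30.0
    bmi_shape: float = 2.0
    bmi_scale: float = 2.5
    bmi_max: float = 60.0
    target_nonsevere_fraction: float = 0.59
    fraction_tolerance: float = 0.05
    hematocrit_mode: str = "fixed"  # "fixed" or "normal"
    hematocrit_mean: float = 0.40
    hematocrit_sd: float = 0.03
    hematocrit_bounds: tuple[float, float] = (0.25, 0.55)


def expected_nonsevere_fraction(config: SyntheticCohortConfig) -> float:
    """Expected P(BMI < 35) under the truncated shifted-Gamma BMI model."""
    cut = (35.0 - config.bmi_offset) / config.bmi_scale
    top = (config.bmi_max - config.bmi_offset) / config.bmi_scale
    return float(gammainc(config.bmi_shape, cut) / gammainc(config.bmi_shape, top))


def _check_feasible(config: SyntheticCohortConfig) -> None:
    expected = expected_nonsevere_fraction(config)
    if abs(expected - config.target_nonsevere_fraction) > config.fraction_tolerance:
        raise ConfigurationError(
            f"BMI model yields expected non-severe fraction {expected:.3f}, "
            f"outside target {config.target_nonsevere_fraction} "
            f"± {config.fraction_tolerance}"
        )


def _draw_heights(
    rng: np.random.Generator, config: SyntheticCohortConfig, sex: Sex, n: int
) -> np.ndarray:
    mu = config.height_mean_cm[sex]
    sd = config.height_sd_cm[sex]
    lo, hi = config.height_bounds_cm
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)


def _draw_bmis(
    rng: np.random.Generator, config: SyntheticCohortConfig, n: int
) -> np.ndarray:
    span = config.bmi_max - config.bmi_offset
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.gamma(config.bmi_shape, config.bmi_scale, size=n - filled)
        keep = draw[draw <= span]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return config.bmi_offset + out


def _draw_hcts(
    rng: np.random.Generator, config: SyntheticCohortConfig, n: int
) -> np.ndarray:
    if config.hematocrit_mode == "fixed":
        return np.full(n, config.hematocrit_mean)
    if config.hematocrit_mode == "normal":
        lo, hi = config.hematocrit_bounds
        a = (lo - config.hematocrit_mean) / config.hematocrit_sd
        b = (hi - config.hematocrit_mean) / config.hematocrit_sd
        return stats.truncnorm.rvs(
            a, b, loc=config.hematocrit_mean, scale=config.hematocrit_sd,
            size=n, random_state=rng,
        )
    raise ConfigurationError(
        f"unknown hematocrit_mode {config.hematocrit_mode!r}"
    )


def generate(config: SyntheticCohortConfig) -> list[PatientRecord]:
    """Generate a cohort; the same config (including seed) is bit-identical."""
    for name, n in (("n_female", config.n_female), ("n_male", config.n_male)):
        if n < 0:
            raise ValidationError(name, "must be non-negative")
    _check_feasible(config)
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    for sex, n, prefix in (
        (Sex.FEMALE, config.n_female, "F"),
        (Sex.MALE, config.n_male, "M"),
    ):
        heights = _draw_heights(rng, config, sex, n)
        bmis = _draw_bmis(rng, config, n)
        hcts = _draw_hcts(rng, config, n)
        for i in range(n):
            weight = bmis[i] * (heights[i] / 100.0) ** 2
            records.append(
                PatientRecord(
                    id=f"{prefix}{i + 1:03d}",
                    sex=sex,
                    height_cm=float(heights[i]),
                    weight_kg=float(weight),
                    hematocrit=float(hcts[i]),
                )
            )
    return records


@dataclass(frozen=True)
class ClassShiftResult:
    """A shifted cohort plus the provenance of the injected shift."""

    records: list[PatientRecord]
    delta_tbv_mL: float
    formula_id: FormulaId
    weight_basis: WeightBasis
    weight_delta_kg: float
    n_shifted: int


def _weight_delta_for(
    delta_tbv_mL: float, formula_id: FormulaId, basis: WeightBasis
) -> float:
    """ABW change that moves the stated formula's TBV by ``delta_tbv_mL``.

    Only formulas linear in weight are supported (Gilcher, Nadler); the
    Lemmens-Bernstein formula is nonlinear in weight through its BMI term, so
    no single weight offset yields a uniform TBV shift.
    """
    if formula_id in GILCHER_CONSTANTS:
        slope = GILCHER_CONSTANTS[formula_id]
    elif formula_id in _NADLER_SLOPE:
        slope = _NADLER_SLOPE[formula_id]
    else:
        raise ConfigurationError(
            f"cannot size a weight shift for {formula_id.value}: "
            "formula is not linear in weight"
        )
    delta_abw = delta_tbv_mL / slope
    if WeightBasis(basis) is WeightBasis.AIBW:
        delta_abw /= _AIBW_DERIVATIVE
    return delta_abw


def inject_class_shift(
    cohort: Sequence[PatientRecord],
    delta_tbv_mL: float,
    formula_id: FormulaId = FormulaId.GILCHER_60,
    weight_basis: WeightBasis = WeightBasis.ABW,
) -> ClassShiftResult:
    """Shift severe-class subjects' weights by a known TBV-equivalent amount.

    Every subject currently in the severe class (BMI >= 35) has their actual
    weight changed so that ``formula_id`` evaluated on ``weight_basis`` moves
    by exactly ``delta_tbv_mL``; a zero delta returns the cohort unchanged.
    Weight gain raises BMI, so severe subjects stay severe for positive
    shifts; negative shifts must not be large enough to demote a subject
    below the class boundary if the recovered contrast is to stay clean.
    """
    if not cohort:
        raise ValidationError("cohort", "must be non-empty")
    if delta_tbv_mL == 0:
        return ClassShiftResult(
            records=list(cohort), delta_tbv_mL=0.0, formula_id=formula_id,
            weight_basis=WeightBasis(weight_basis), weight_delta_kg=0.0,
            n_shifted=0,
        )
    dw = _weight_delta_for(delta_tbv_mL, formula_id, weight_basis)
    shifted, n_shifted = [], 0
    for rec in cohort:
        bmi = compute_bmi(rec.height_cm, rec.weight_kg)
        if classify_obesity(bmi) is ObesityClass.SEVERE:
            shifted.append(replace(rec, weight_kg=rec.weight_kg + dw))
            n_shifted += 1
        else:
            shifted.append(rec)
    return ClassShiftResult(
        records=shifted,
        delta_tbv_mL=delta_tbv_mL,
        formula_id=formula_id,
        weight_basis=WeightBasis(weight_basis),
        weight_delta_kg=dw,
        n_shifted=n_shifted,
    )
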