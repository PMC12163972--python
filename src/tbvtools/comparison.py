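"""Cohort-level formula comparison.

Four analyses run over a cohort's per-patient estimate sets:

* pairwise difference curves between two formulas across BMI, judged against
  a functional-significance threshold (500 mL by default -- roughly one
  plasma unit at hematocrit 40%, and 2-3 L of processed volume in a 5-6x
  collection);
* expected-range coverage per formula and sex (obese men 4000-7000 mL,
  obese women 3500-6500 mL, inclusive bounds);
* min / median / max summaries per formula;
* a two-tailed two-sample t test of mean TBV between non-severe
  (BMI 30.0-34.9) and severe (BMI >= 35.0) obesity, Welch by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .anthropometry import ObesityClass, Sex, classify_obesity
from .errors import DataError, StatisticsError
from .estimators import EstimateKey, EstimateSet, FormulaId, WeightBasis

__all__ = [
    "DifferencePoint",
    "RangeCoverage",
    "GroupComparison",
    "FUNCTIONAL_THRESHOLD_ML",
    "EXPECTED_RANGES_ML",
    "difference_curve",
    "range_coverage",
    "best_performing",
    "summarize_formula",
    "compare_severity_groups",
    "group_comparison_from_values",
]

FUNCTIONAL_THRESHOLD_ML = 500.0

# Empirical plausibility bands for estimated TBV in obese adults, mL.
EXPECTED_RANGES_ML: dict[Sex, tuple[float, float]] = {
    Sex.MALE: (4000.0, 7000.0),
    Sex.FEMALE: (3500.0, 6500.0),
}


@dataclass(frozen=True)
class DifferencePoint:
    patient_id: str
    bmi: float
    formula_a: EstimateKey
    formula_b: EstimateKey
    delta_mL: float  # tbv_a - tbv_b
    significant: bool  # |delta| >= threshold (inclusive)


@dataclass(frozen=True)
class RangeCoverage:
    formula: EstimateKey
    sex: Sex
    range_low_mL: float
    range_high_mL: float
    n_within: int
    n_under: int
    n_over: int

    @property
    def n_total(self) -> int:
        return self.n_within + self.n_under + self.n_over

    @property
    def fraction_within(self) -> float:
        return self.n_within / self.n_total if self.n_total else math.nan


@dataclass(frozen=True)
class GroupComparison:
    formula: EstimateKey
    sex: Optional[Sex]
    n_nonsevere: int
    n_severe: int
    mean_nonsevere_mL: float
    sd_nonsevere_mL: float
    mean_severe_mL: float
    sd_severe_mL: float
    mean_difference_mL: float  # severe - nonsevere
    t_statistic: float
    p_value: float
    functionally_significant: bool


def _require(est: EstimateSet, key: EstimateKey) -> float:
    if key not in est:
        fid, basis = key
        raise DataError(
            f"patient {est.patient_id}: estimate {fid.value}/{basis.value} missing"
        )
    return est.estimates[key].tbv_mL


def difference_curve(
    estimate_sets: Iterable[EstimateSet],
    formula_a: EstimateKey,
    formula_b: EstimateKey,
    threshold_mL: float = FUNCTIONAL_THRESHOLD_ML,
) -> list[DifferencePoint]:
    """Per-patient TBV difference (a minus b), sorted by (BMI, patient id).

    A point is functionally significant when |delta| >= threshold; the
    boundary is inclusive.
    """
    points = []
    for est in estimate_sets:
        delta = _require(est, formula_a) - _require(est, formula_b)
        points.append(
            DifferencePoint(
                patient_id=est.patient_id,
                bmi=est.bmi,
                formula_a=formula_a,
                formula_b=formula_b,
                delta_mL=delta,
                significant=abs(delta) >= threshold_mL,
            )
        )
    points.sort(key=lambda p: (p.bmi, p.patient_id))
    return points


def range_coverage(
    estimate_sets: Iterable[EstimateSet],
    formula: EstimateKey,
    sex: Sex,
    expected_range: Optional[tuple[float, float]] = None,
) -> RangeCoverage:
    """Count estimates under / within / over the expected range (inclusive).

    All supplied estimate sets must belong to ``sex``; the default range is
    the sex-specific empirical band.
    """
    low, high = expected_range if expected_range else EXPECTED_RANGES_ML[sex]
    n_within = n_under = n_over = 0
    for est in estimate_sets:
        if est.sex is not sex:
            raise DataError(
                f"patient {est.patient_id}: sex {est.sex.value} does not match "
                f"coverage group {sex.value}"
            )
        tbv = _require(est, formula)
        if tbv < low:
            n_under += 1
        elif tbv > high:
            n_over += 1
        else:
            n_within += 1
    return RangeCoverage(
        formula=formula,
        sex=sex,
        range_low_mL=low,
        range_high_mL=high,
        n_within=n_within,
        n_under=n_under,
        n_over=n_over,
    )


def best_performing(coverages: Sequence[RangeCoverage]) -> RangeCoverage:
    """The formula with the highest fraction of estimates inside the range."""
    if not coverages:
        raise DataError("no coverage results to rank")
    return max(coverages, key=lambda c: (-1.0 if math.isnan(c.fraction_within)
                                         else c.fraction_within))


def summarize_formula(
    estimate_sets: Sequence[EstimateSet], formula: EstimateKey
) -> tuple[float, float, float]:
    """(min, median, max) of one formula's TBV across the cohort.

    The median uses the midpoint of the two central order statistics for
    even-sized cohorts.
    """
    values = [_require(est, formula) for est in estimate_sets]
    if not values:
        raise DataError("summarize_formula requires a non-empty cohort")
    arr = np.asarray(values, dtype=float)
    return float(arr.min()), float(np.median(arr)), float(arr.max())


def group_comparison_from_values(
    nonsevere_mL: Sequence[float],
    severe_mL: Sequence[float],
    formula: EstimateKey = (FormulaId.LEMMENS_BERNSTEIN, WeightBasis.ABW),
    sex: Optional[Sex] = None,
    threshold_mL: float = FUNCTIONAL_THRESHOLD_ML,
    equal_var: bool = False,
) -> GroupComparison:
    """Two-tailed two-sample t test on raw per-patient TBV values.

    Welch's unequal-variance form by default; set ``equal_var=True`` for the
    pooled-variance test (equivalent to a Gaussian GLM with a single binary
    class predictor).  Requires at least two patients per class.
    """
    a = np.asarray(nonsevere_mL, dtype=float)
    b = np.asarray(severe_mL, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatisticsError(
            f"need >= 2 patients per class, got {a.size} non-severe / {b.size} severe"
        )
    res = stats.ttest_ind(b, a, equal_var=equal_var)
    diff = float(b.mean() - a.mean())
    return GroupComparison(
        formula=formula,
        sex=sex,
        n_nonsevere=int(a.size),
        n_severe=int(b.size),
        mean_nonsevere_mL=float(a.mean()),
        sd_nonsevere_mL=float(a.std(ddof=1)),
        mean_severe_mL=float(b.mean()),
        sd_severe_mL=float(b.std(ddof=1)),
        mean_difference_mL=diff,
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        functionally_significant=abs(diff) >= threshold_mL,
    )


def compare_severity_groups(
    estimate_sets: Iterable[EstimateSet],
    formula: EstimateKey,
    sex: Optional[Sex] = None,
    threshold_mL: float = FUNCTIONAL_THRESHOLD_ML,
    equal_var: bool = False,
) -> GroupComparison:
    """Compare mean TBV between non-severe and severe obesity.

    Patients are classed by their BMI (non-severe 30.0-34.9, severe >= 35.0
    with morbid merged in); non-obese records are excluded.  When ``sex`` is
    given only that sex's records enter the comparison.
    """
    nonsevere, severe = [], []
    for est in estimate_sets:
        if sex is not None and est.sex is not sex:
            continue
        cls = classify_obesity(est.bmi)
        if cls is ObesityClass.NON_SEVERE:
            nonsevere.append(_require(est, formula))
        elif cls is ObesityClass.SEVERE:
            severe.append(_require(est, formula))
    return group_comparison_from_values(
        nonsevere, severe, formula=formula, sex=sex,
        threshold_mL=threshold_mL, equal_var=equal_var,
    )
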