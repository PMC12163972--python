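"""End-to-end orchestration.

Two entry points:

* :func:`hypothetical_patient_tables` — the standardized single-patient
  exercise: every formula evaluated on one fixed patient (173 cm, 120 kg,
  hematocrit 40% by default), with exchange and collection parameters
  derived from each estimate.  Following the convention of the standardized
  exercise, a single AIBW computed with the *male* Devine intercept is used
  for every formula row, including the female variants, so that rows differ
  only in formula constants.
* :func:`run_pipeline` — the cohort analysis: per-patient estimate sets,
  pairwise difference curves by sex, expected-range coverage, per-formula
  summaries and the severity-group comparison.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .anthropometry import (
    PatientRecord,
    Sex,
    adjusted_ibw,
    compute_bmi,
    devine_ibw,
    profile_for,
)
from .comparison import (
    DifferencePoint,
    GroupComparison,
    RangeCoverage,
    best_performing,
    compare_severity_groups,
    difference_curve,
    range_coverage,
    summarize_formula,
)
from .config import RunConfig
from .errors import ConfigurationError, StatisticsError
from .estimators import (
    EstimateKey,
    EstimateSet,
    FormulaId,
    WeightBasis,
    estimate_all,
    gilcher,
    lemmens_bernstein,
    nadler,
)
from .io import fmt_hours, fmt_mL
from .planning import plan_collection, plan_rce, plan_tpe

logger = logging.getLogger(__name__)

__all__ = [
    "HYPOTHETICAL_PATIENT",
    "hypothetical_estimates",
    "hypothetical_patient_tables",
    "AnalysisBundle",
    "run_pipeline",
]

# The standardized patient: 173 cm, 120 kg (BMI 40), hematocrit 40%.
HYPOTHETICAL_PATIENT = dict(height_cm=173.0, weight_kg=120.0, hematocrit=0.40)

# Row order of the standardized-exercise tables.
_HYPOTHETICAL_ROWS: tuple[tuple[str, FormulaId], ...] = (
    ("Lemmens-Bernstein", FormulaId.LEMMENS_BERNSTEIN),
    ("Gilcher's rule AIBW-60", FormulaId.GILCHER_60),
    ("Gilcher's rule AIBW-55", FormulaId.GILCHER_55),
    ("Nadler's AIBW female", FormulaId.NADLER_FEMALE),
    ("Nadler's AIBW male", FormulaId.NADLER_MALE),
)


def hypothetical_estimates(
    height_cm: float = 173.0,
    weight_kg: float = 120.0,
    config: Optional[RunConfig] = None,
) -> dict[FormulaId, float]:
    """Full-precision TBV for every formula on the standardized patient.

    The AIBW is computed once from the male Devine IBW and fed to every
    AIBW-based row, female variants included.
    """
    config = config or RunConfig()
    ibw = devine_ibw(Sex.MALE, height_cm)
    aibw = adjusted_ibw(ibw, weight_kg)
    constants = config.gilcher_constants
    return {
        FormulaId.LEMMENS_BERNSTEIN: lemmens_bernstein(height_cm, weight_kg),
        FormulaId.GILCHER_60: gilcher(aibw, constants[FormulaId.GILCHER_60]),
        FormulaId.GILCHER_55: gilcher(aibw, constants[FormulaId.GILCHER_55]),
        FormulaId.NADLER_FEMALE: nadler(Sex.FEMALE, height_cm, aibw),
        FormulaId.NADLER_MALE: nadler(Sex.MALE, height_cm, aibw),
    }


def hypothetical_patient_tables(
    height_cm: float = 173.0,
    weight_kg: float = 120.0,
    hematocrit: float = 0.40,
    config: Optional[RunConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The standardized-exercise exchange and collection tables.

    Returns ``(exchange, collection)``: the first holds TBV, RCV, TPV and
    RBC/plasma unit counts per formula; the second the multi-volume
    collection volume and duration.  All volumes are reported in integer mL
    (round half up) and durations to 0.1 h.
    """
    config = config or RunConfig()
    tbvs = hypothetical_estimates(height_cm, weight_kg, config)
    exchange_rows, collection_rows = [], []
    for label, formula_id in _HYPOTHETICAL_ROWS:
        tbv = tbvs[formula_id]
        rce = plan_rce(
            tbv, hematocrit, fcr=config.fcr, unit_rcv_mL=config.rbc_unit_mL,
            model=config.rce_model, rounding=config.unit_rounding,
        )
        tpe = plan_tpe(
            tbv, hematocrit, plasma_volumes=config.plasma_volumes,
            unit_plasma_mL=config.plasma_unit_mL, rounding=config.unit_rounding,
        )
        coll = plan_collection(
            tbv, multiplier=config.collection_multiplier,
            flow_mL_per_min=config.flow_mL_per_min,
        )
        exchange_rows.append(
            {
                "formula": label,
                "tbv_mL": fmt_mL(tbv),
                "rcv_mL": fmt_mL(rce.rcv_mL),
                "tpv_mL": fmt_mL(rce.tpv_mL),
                "rbc_units": rce.units,
                "plasma_units": tpe.units,
            }
        )
        collection_rows.append(
            {
                "formula": label,
                "tbv_mL": fmt_mL(tbv),
                "process_volume_mL": coll.process_volume_report_mL,
                "hours": fmt_hours(coll.duration_h),
            }
        )
    return pd.DataFrame(exchange_rows), pd.DataFrame(collection_rows)


@dataclass
class AnalysisBundle:
    """Everything a cohort run produces."""

    config: RunConfig
    cohort: list[PatientRecord]
    excluded: list[PatientRecord]
    estimate_sets: list[EstimateSet]
    differences: dict[tuple[Sex, EstimateKey, EstimateKey], list[DifferencePoint]]
    coverage: list[RangeCoverage]
    best_by_sex: dict[Sex, RangeCoverage]
    summaries: dict[tuple[Sex, EstimateKey], tuple[float, float, float]]
    group_comparisons: list[GroupComparison]
    report: dict = field(default_factory=dict)


def run_pipeline(cohort: Sequence[PatientRecord], config: Optional[RunConfig] = None) -> AnalysisBundle:
    """Run the full cohort analysis.

    Applies the obesity inclusion filter, builds estimate sets from the
    configured formula matrix, then computes all pairwise difference curves,
    expected-range coverage, per-formula summaries and severity-group
    comparisons separately for women and men.  Deterministic for a given
    cohort and configuration.
    """
    config = config or RunConfig()
    if not config.formulas:
        raise ConfigurationError("run configuration lists no formulas")

    included, excluded = [], []
    for rec in cohort:
        bmi = compute_bmi(rec.height_cm, rec.weight_kg)
        if bmi in (30.0, 35.0):
            logger.info("patient %s sits exactly on a class boundary (BMI %.1f)",
                        rec.id, bmi)
        (included if config.includes_bmi(bmi) else excluded).append(rec)
    logger.info("cohort: %d included, %d excluded by the BMI >=%s 30 filter",
                len(included), len(excluded),
                "" if config.inclusion_inclusive else " (strict)")

    estimate_sets = [
        estimate_all(rec, profile_for(rec), config.formulas,
                     config.gilcher_constants)
        for rec in included
    ]

    by_sex = {
        sex: [e for e in estimate_sets if e.sex is sex]
        for sex in (Sex.FEMALE, Sex.MALE)
    }

    differences: dict = {}
    coverage: list[RangeCoverage] = []
    summaries: dict = {}
    group_comparisons: list[GroupComparison] = []
    best_by_sex: dict[Sex, RangeCoverage] = {}

    for sex, sets in by_sex.items():
        if not sets:
            continue
        keys = sorted(sets[0].estimates.keys(),
                      key=lambda k: (k[0].value, k[1].value))
        for key_a, key_b in itertools.combinations(keys, 2):
            differences[(sex, key_a, key_b)] = difference_curve(
                sets, key_a, key_b, threshold_mL=config.functional_threshold_mL
            )
        sex_coverage = [
            range_coverage(sets, key, sex, config.expected_range(sex))
            for key in keys
        ]
        coverage.extend(sex_coverage)
        best_by_sex[sex] = best_performing(sex_coverage)
        for key in keys:
            summaries[(sex, key)] = summarize_formula(sets, key)
            try:
                group_comparisons.append(
                    compare_severity_groups(
                        sets, key, sex=sex,
                        threshold_mL=config.functional_threshold_mL,
                        equal_var=config.equal_var,
                    )
                )
            except StatisticsError as exc:
                logger.warning("severity comparison skipped for %s/%s %s: %s",
                               key[0].value, key[1].value, sex.value, exc)

    report = {
        "config_hash": config.hash,
        "seed": config.seed,
        "n_input": len(cohort),
        "n_included": len(included),
        "n_excluded": len(excluded),
        "n_female": len(by_sex[Sex.FEMALE]),
        "n_male": len(by_sex[Sex.MALE]),
        "best_performing": {
            sex.value: f"{c.formula[0].value}/{c.formula[1].value}"
            for sex, c in best_by_sex.items()
        },
    }
    return AnalysisBundle(
        config=config,
        cohort=list(included),
        excluded=excluded,
        estimate_sets=estimate_sets,
        differences=differences,
        coverage=coverage,
        best_by_sex=best_by_sex,
        summaries=summaries,
        group_comparisons=group_comparisons,
        report=report,
    )
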