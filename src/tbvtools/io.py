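"""Cohort CSV reading/validation and results writers.

Cohort files are plain CSV with header columns ``id, sex, height_cm,
weight_kg, hematocrit`` (hematocrit optional; missing values filled with the
configured default).  Sex tokens are case-insensitive {male, female, M, F}.

Results files follow a frozen formatting contract so runs are byte
comparable: volumes in integer mL (round half up), hours to 0.1 h, p values
to three significant digits.  Each results file starts with ``#``-prefixed
provenance lines (package version, config hash, seed) which pandas skips on
re-read via ``comment='#'``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import __version__
from .anthropometry import PatientRecord, Sex
from .comparison import DifferencePoint, GroupComparison, RangeCoverage
from .config import RunConfig
from .errors import DataError
from .rounding import round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "read_cohort",
    "write_cohort",
    "fmt_mL",
    "fmt_hours",
    "fmt_pvalue",
    "write_results_csv",
    "differences_frame",
    "coverage_frame",
    "groups_frame",
]

_REQUIRED_COLUMNS = ("id", "sex", "height_cm", "weight_kg")


def read_cohort(path: str | Path, hct_default: float = 0.40) -> list[PatientRecord]:
    """Read and validate a cohort CSV.

    Malformed rows are collected and reported together with their line
    numbers in a single :class:`DataError`; duplicate ids are rejected.  An
    empty file (header only) yields an empty cohort with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype={"id": str}, comment="#",
                     float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cohort file {path} missing columns: {missing}")
    if df.empty:
        logger.warning("cohort file %s contains a header but no rows", path)
        return []
    records: list[PatientRecord] = []
    problems: list[str] = []
    seen_ids: set[str] = set()
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            pid = str(row["id"]).strip()
            if not pid or pid.lower() == "nan":
                raise DataError("empty patient id")
            if pid in seen_ids:
                raise DataError(f"duplicate patient id {pid!r}")
            hct = row.get("hematocrit")
            if hct is None or pd.isna(hct):
                hct = hct_default
            records.append(
                PatientRecord(
                    id=pid,
                    sex=Sex.parse(row["sex"]),
                    height_cm=float(row["height_cm"]),
                    weight_kg=float(row["weight_kg"]),
                    hematocrit=float(hct),
                )
            )
            seen_ids.add(pid)
        except (DataError, ValueError, Exception) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise DataError(
            f"cohort file {path}: {len(problems)} invalid row(s)\n  "
            + "\n  ".join(problems)
        )
    return records


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write patient records to CSV in the canonical column order."""
    rows = [
        {
            "id": r.id,
            "sex": r.sex.value,
            "height_cm": r.height_cm,
            "weight_kg": r.weight_kg,
            "hematocrit": r.hematocrit,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=["id", "sex", "height_cm", "weight_kg",
                                        "hematocrit"])
    # %.17g round-trips IEEE doubles exactly through text
    frame.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------- formatting

def fmt_mL(value: float) -> int:
    return int(round_half_up(value))


def fmt_hours(value: float) -> float:
    return round_half_up(value, 1)


def fmt_pvalue(value: float) -> str:
    return f"{value:.3g}"


def _provenance_lines(config: Optional[RunConfig], seed: Optional[int]) -> list[str]:
    lines = [f"# tbvtools {__version__}"]
    if config is not None:
        lines.append(f"# config_hash {config.hash}")
    if seed is not None:
        lines.append(f"# seed {seed}")
    return lines


def write_results_csv(
    frame: pd.DataFrame,
    path: str | Path,
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
) -> None:
    """Write a results table with provenance header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _provenance_lines(config, seed):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)


# ------------------------------------------------------- tables from results

def differences_frame(points: Sequence[DifferencePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "bmi": round_half_up(p.bmi, 2),
                "formula_a": f"{p.formula_a[0].value}/{p.formula_a[1].value}",
                "formula_b": f"{p.formula_b[0].value}/{p.formula_b[1].value}",
                "delta_mL": fmt_mL(p.delta_mL),
                "significant": p.significant,
            }
            for p in points
        ],
        columns=["patient_id", "bmi", "formula_a", "formula_b", "delta_mL",
                 "significant"],
    )


def coverage_frame(coverages: Sequence[RangeCoverage]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "formula": f"{c.formula[0].value}/{c.formula[1].value}",
                "sex": c.sex.value,
                "range_low_mL": fmt_mL(c.range_low_mL),
                "range_high_mL": fmt_mL(c.range_high_mL),
                "n_under": c.n_under,
                "n_within": c.n_within,
                "n_over": c.n_over,
                "fraction_within": round_half_up(c.fraction_within, 3)
                if c.n_total
                else float("nan"),
            }
            for c in coverages
        ],
        columns=["formula", "sex", "range_low_mL", "range_high_mL",
                 "n_under", "n_within", "n_over", "fraction_within"],
    )


def groups_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "formula": f"{g.formula[0].value}/{g.formula[1].value}",
                "sex": g.sex.value if g.sex else "all",
                "n_nonsevere": g.n_nonsevere,
                "n_severe": g.n_severe,
                "mean_nonsevere_mL": fmt_mL(g.mean_nonsevere_mL),
                "mean_severe_mL": fmt_mL(g.mean_severe_mL),
                "mean_difference_mL": fmt_mL(g.mean_difference_mL),
                "t_statistic": round_half_up(g.t_statistic, 3),
                "p_value": fmt_pvalue(g.p_value),
                "functionally_significant": g.functionally_significant,
            }
            for g in comparisons
        ],
        columns=["formula", "sex", "n_nonsevere", "n_severe",
                 "mean_nonsevere_mL", "mean_severe_mL", "mean_difference_mL",
                 "t_statistic", "p_value", "functionally_significant"],
    )
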