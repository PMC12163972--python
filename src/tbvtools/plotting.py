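"""Matplotlib views of the cohort analysis: TBV-vs-BMI curves with the
shaded expected range, difference curves with the ±threshold band, and
severity-group mean bars."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .anthropometry import Sex
from .comparison import DifferencePoint, GroupComparison
from .estimators import EstimateKey, EstimateSet

__all__ = ["plot_tbv_vs_bmi", "plot_difference_curve", "plot_group_means"]


def _label(key: EstimateKey) -> str:
    return f"{key[0].value}/{key[1].value}"


def plot_tbv_vs_bmi(
    estimate_sets: Sequence[EstimateSet],
    keys: Sequence[EstimateKey],
    expected_range: tuple[float, float],
    sex: Optional[Sex] = None,
    ax: Optional[plt.Axes] = None,
) -> plt.Axes:
    """Per-formula TBV across BMI with the expected range shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    sets = sorted(estimate_sets, key=lambda e: (e.bmi, e.patient_id))
    bmi = [e.bmi for e in sets]
    ax.axhspan(*expected_range, color="0.85", zorder=0,
               label="expected range")
    for key in keys:
        ax.plot(bmi, [e.tbv(*key) for e in sets], marker=".", lw=1,
                label=_label(key))
    ax.set_xlabel("BMI (kg/m²)")
    ax.set_ylabel("estimated TBV (mL)")
    if sex:
        ax.set_title(f"Estimated TBV across BMI, {sex.value}")
    ax.legend(fontsize=8)
    return ax


def plot_difference_curve(
    points: Sequence[DifferencePoint],
    threshold_mL: float = 500.0,
    ax: Optional[plt.Axes] = None,
) -> plt.Axes:
    """TBV difference across BMI with dashed ±threshold lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    bmi = [p.bmi for p in points]
    ax.plot(bmi, [p.delta_mL for p in points], marker=".", lw=1, color="C0")
    for y in (threshold_mL, -threshold_mL):
        ax.axhline(y, color="red", ls="--", lw=1)
    ax.axhline(0, color="0.5", lw=0.8)
    if points:
        ax.set_title(f"{_label(points[0].formula_a)} − {_label(points[0].formula_b)}")
    ax.set_xlabel("BMI (kg/m²)")
    ax.set_ylabel("ΔTBV (mL)")
    return ax


def plot_group_means(
    comparisons: Sequence[GroupComparison], ax: Optional[plt.Axes] = None
) -> plt.Axes:
    """Grouped bars of mean TBV in non-severe vs severe obesity."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    x = np.arange(len(comparisons))
    width = 0.38
    ax.bar(x - width / 2, [c.mean_nonsevere_mL for c in comparisons], width,
           yerr=[c.sd_nonsevere_mL for c in comparisons], capsize=3,
           label="non-severe (BMI 30.0–34.9)")
    ax.bar(x + width / 2, [c.mean_severe_mL for c in comparisons], width,
           yerr=[c.sd_severe_mL for c in comparisons], capsize=3,
           label="severe (BMI ≥ 35.0)")
    ax.set_xticks(x)
    ax.set_xticklabels([_label(c.formula) for c in comparisons],
                       rotation=20, ha="right", fontsize=8)
    ax.set_ylabel("mean estimated TBV (mL)")
    ax.legend(fontsize=8)
    return ax
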