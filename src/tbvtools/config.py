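"""Run configuration: the formula/basis matrix, procedure constants,
thresholds and rounding conventions, loadable from YAML with flag overrides.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

from .anthropometry import Sex
from .errors import ConfigurationError
from .estimators import DEFAULT_FORMULA_MATRIX, FormulaId, WeightBasis
from .planning import ExchangeModel, UnitRounding

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on besides the cohort itself."""

    formulas: tuple[tuple[str, WeightBasis], ...] = DEFAULT_FORMULA_MATRIX
    gilcher_male_mL_per_kg: float = 60.0
    gilcher_female_mL_per_kg: float = 55.0
    functional_threshold_mL: float = 500.0
    expected_range_male_mL: tuple[float, float] = (4000.0, 7000.0)
    expected_range_female_mL: tuple[float, float] = (3500.0, 6500.0)
    hematocrit_default: float = 0.40
    fcr: float = 0.30
    plasma_volumes: float = 1.0
    rbc_unit_mL: float = 200.0
    plasma_unit_mL: float = 300.0
    collection_multiplier: float = 5.0
    flow_mL_per_min: float = 80.0
    rce_model: ExchangeModel = ExchangeModel.EXPONENTIAL
    unit_rounding: UnitRounding = UnitRounding.HALF_UP
    # True: obesity filter keeps BMI == 30.0 exactly (BMI >= 30);
    # False: strict BMI > 30.
    inclusion_inclusive: bool = True
    equal_var: bool = False  # pooled-variance t test instead of Welch
    seed: int = 0

    def __post_init__(self):
        for name in (
            "gilcher_male_mL_per_kg", "gilcher_female_mL_per_kg",
            "functional_threshold_mL", "rbc_unit_mL", "plasma_unit_mL",
            "flow_mL_per_min",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("expected_range_male_mL", "expected_range_female_mL"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(f"{name}: low must be < high")
        object.__setattr__(
            self,
            "formulas",
            tuple((str(f), WeightBasis(b)) for f, b in self.formulas),
        )

    @property
    def gilcher_constants(self) -> dict[FormulaId, float]:
        return {
            FormulaId.GILCHER_60: self.gilcher_male_mL_per_kg,
            FormulaId.GILCHER_55: self.gilcher_female_mL_per_kg,
        }

    def expected_range(self, sex: Sex) -> tuple[float, float]:
        return (
            self.expected_range_male_mL
            if sex is Sex.MALE
            else self.expected_range_female_mL
        )

    def includes_bmi(self, bmi: float) -> bool:
        return bmi >= 30.0 if self.inclusion_inclusive else bmi > 30.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["formulas"] = [[f, b.value] for f, b in self.formulas]
        d["rce_model"] = self.rce_model.value
        d["unit_rounding"] = self.unit_rounding.value
        return d

    @property
    def hash(self) -> str:
        """Short stable digest of the configuration, for provenance headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def load_config(path: Optional[str | Path] = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "formulas" in data:
        data["formulas"] = tuple(
            (item[0], WeightBasis(item[1])) for item in data["formulas"]
        )
    known = RunConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "rce_model" in data:
        data["rce_model"] = ExchangeModel(data["rce_model"])
    if "unit_rounding" in data:
        data["unit_rounding"] = UnitRounding(data["unit_rounding"])
    for key in ("expected_range_male_mL", "expected_range_female_mL"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)
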