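"""Apheresis procedure planning from a TBV estimate.

Given an estimated total blood volume and hematocrit this module derives the
blood compartment volumes and the parameters of the three procedure types
whose dosing depends on them:

* red blood cell exchange (RCE): replacement RBC units to reach a target
  fraction of cells remaining (FCR), assuming isovolemic exchange in which
  native red cells deplete exponentially, so the replaced red-cell volume is
  ``RCV * ln(1/FCR)``;
* therapeutic plasma exchange (TPE): plasma units for an N-volume exchange,
  replaced volume ``N * TPV``;
* cell collections processing a multiple of the TBV at a fixed flow rate.

Unit counts and durations are rounded half-up at report time (units to
integers, hours to 0.1 h); a conservative ceiling mode for unit counts is
available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import ValidationError
from .rounding import ceil_units, round_half_up

__all__ = [
    "ExchangeModel",
    "UnitRounding",
    "ExchangePlan",
    "CollectionPlan",
    "blood_compartments",
    "rce_replaced_volume",
    "plan_rce",
    "plan_tpe",
    "plan_collection",
]


class ExchangeModel(str, Enum):
    """How the RCE replaced volume relates to RCV and the FCR target."""

    EXPONENTIAL = "exponential"  # replaced = rcv * ln(1/fcr), isovolemic
    LINEAR = "linear"            # replaced = rcv * (1 - fcr), bulk removal


class UnitRounding(str, Enum):
    HALF_UP = "half_up"
    CEILING = "ceiling"


def blood_compartments(tbv_mL: float, hematocrit: float) -> tuple[float, float]:
    """Split TBV into red cell volume and plasma volume, full precision.

    rcv = tbv * hct, tpv = tbv * (1 - hct); the two always sum back to tbv.
    """
    if tbv_mL <= 0:
        raise ValidationError("tbv_mL", "must be positive")
    if not (0.0 < hematocrit < 1.0):
        raise ValidationError("hematocrit", f"{hematocrit} outside (0, 1)")
    rcv = tbv_mL * hematocrit
    return rcv, tbv_mL - rcv


def rce_replaced_volume(
    rcv_mL: float, fcr: float, model: ExchangeModel = ExchangeModel.EXPONENTIAL
) -> float:
    """Red-cell volume to replace to bring native cells down to ``fcr``."""
    if not (0.0 < fcr <= 1.0):
        raise ValidationError(
            "fcr", f"{fcr} outside (0, 1]; fcr = 0 would require infinite exchange"
        )
    model = ExchangeModel(model)
    if model is ExchangeModel.EXPONENTIAL:
        return rcv_mL * math.log(1.0 / fcr)
    return rcv_mL * (1.0 - fcr)


@dataclass(frozen=True)
class ExchangePlan:
    """Derived parameters of one exchange procedure."""

    tbv_mL: float
    rcv_mL: float
    tpv_mL: float
    procedure: str  # "rce" or "tpe"
    replaced_volume_mL: float
    unit_volume_mL: float
    units: int
    fcr: Optional[float] = None               # rce only
    plasma_volumes_exchanged: Optional[float] = None  # tpe only


@dataclass(frozen=True)
class CollectionPlan:
    """A multi-volume cell collection: volume processed and duration."""

    tbv_mL: float
    multiplier: float
    flow_mL_per_min: float
    process_volume_mL: float  # full precision; round at report time

    @property
    def duration_h(self) -> float:
        return self.process_volume_mL / (self.flow_mL_per_min * 60.0)

    @property
    def process_volume_report_mL(self) -> int:
        return int(round_half_up(self.process_volume_mL))

    @property
    def duration_report_h(self) -> float:
        return round_half_up(self.duration_h, 1)


def _units(replaced_mL: float, unit_mL: float, rounding: UnitRounding) -> int:
    if unit_mL <= 0:
        raise ValidationError("unit_volume_mL", "must be positive")
    raw = replaced_mL / unit_mL
    if UnitRounding(rounding) is UnitRounding.CEILING:
        return ceil_units(raw)
    return int(round_half_up(raw))


def plan_rce(
    tbv_mL: float,
    hematocrit: float,
    fcr: float = 0.30,
    unit_rcv_mL: float = 200.0,
    model: ExchangeModel = ExchangeModel.EXPONENTIAL,
    rounding: UnitRounding = UnitRounding.HALF_UP,
) -> ExchangePlan:
    """Plan a red blood cell exchange.

    ``unit_rcv_mL`` is the erythrocyte content of one standard RBC unit
    (200 mL by default), not the bag volume.
    """
    rcv, tpv = blood_compartments(tbv_mL, hematocrit)
    replaced = rce_replaced_volume(rcv, fcr, model)
    return ExchangePlan(
        tbv_mL=tbv_mL,
        rcv_mL=rcv,
        tpv_mL=tpv,
        procedure="rce",
        replaced_volume_mL=replaced,
        unit_volume_mL=unit_rcv_mL,
        units=_units(replaced, unit_rcv_mL, rounding),
        fcr=fcr,
    )


def plan_tpe(
    tbv_mL: float,
    hematocrit: float,
    plasma_volumes: float = 1.0,
    unit_plasma_mL: float = 300.0,
    rounding: UnitRounding = UnitRounding.HALF_UP,
) -> ExchangePlan:
    """Plan a therapeutic plasma exchange of ``plasma_volumes`` TPVs."""
    if plasma_volumes < 0:
        raise ValidationError("plasma_volumes", "must be non-negative")
    rcv, tpv = blood_compartments(tbv_mL, hematocrit)
    replaced = plasma_volumes * tpv
    return ExchangePlan(
        tbv_mL=tbv_mL,
        rcv_mL=rcv,
        tpv_mL=tpv,
        procedure="tpe",
        replaced_volume_mL=replaced,
        unit_volume_mL=unit_plasma_mL,
        units=_units(replaced, unit_plasma_mL, rounding),
        plasma_volumes_exchanged=plasma_volumes,
    )


def plan_collection(
    tbv_mL: float, multiplier: float = 5.0, flow_mL_per_min: float = 80.0
) -> CollectionPlan:
    """Plan a cell collection processing ``multiplier`` blood volumes."""
    if tbv_mL <= 0:
        raise ValidationError("tbv_mL", "must be positive")
    if multiplier < 0:
        raise ValidationError("multiplier", "must be non-negative")
    if flow_mL_per_min <= 0:
        raise ValidationError("flow_mL_per_min", "must be positive")
    return CollectionPlan(
        tbv_mL=tbv_mL,
        multiplier=multiplier,
        flow_mL_per_min=flow_mL_per_min,
        process_volume_mL=multiplier * tbv_mL,
    )
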