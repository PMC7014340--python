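"""The OECD empirical load -> in-lake TP concentration model.

Given an annual TP load L (kg/yr), outflow discharge Q (m3/yr) and lake
residence time tau (yr), the inflow concentration is

    TP_in = L / Q * 1e6            [ug P/l]

and the in-lake annual mean concentration is

    TP_lake = a * (TP_in / (1 + sqrt(tau)))**b

with (a, b) either the shallow-lakes preset (1.02, 0.88) or the combined
cross-lake preset (1.55, 0.82), selected by mean depth against a 3.0 m
threshold.  The model is exactly invertible, which supports headroom
("how much extra load before the next class boundary") calculations, and
at fixed hydrology it implies the pure power-law scaling C = C0*(L/L0)**b
used for quick recalculations from a calibrated (load, concentration)
pair.

Note the model is empirical: with a > 1 it can predict TP_lake > TP_in at
very low inflow concentrations.  Predictions are reported unclipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_types import (
    DomainError,
    NoFlushingError,
    OecdParameters,
    OecdPreset,
    WaterBody,
)
from .hydrology import residence_time

__all__ = [
    "LakePrediction",
    "select_parameters",
    "lake_concentration",
    "load_for_concentration",
    "scale_concentration",
]

#: kg/yr over m3/yr to ug/l.
_KG_PER_M3_TO_UG_PER_L = 1.0e6


@dataclass(frozen=True)
class LakePrediction:
    """Outputs of one lake-model evaluation."""

    tp_inflow: float      # ug P/l
    inflow_term: float    # X = TP_in / (1 + sqrt(tau)), ug P/l
    tp_lake: float        # ug P/l
    residence_time_yr: float
    preset_name: str      # 'shallow' or 'combined'

    @property
    def retention_fraction(self) -> float:
        """R = 1 - TP_lake/TP_in; may be negative at very low inflow TP."""
        if self.tp_inflow <= 0:
            return 0.0
        return 1.0 - self.tp_lake / self.tp_inflow


def select_parameters(
    mean_depth_m: float, params: OecdParameters
) -> tuple[OecdPreset, str]:
    """Pick the (a, b) preset for a lake of the given mean depth.

    Depths at or below the threshold (default 3.0 m) take the shallow
    preset; deeper lakes take the combined preset.
    """
    if not mean_depth_m > 0:
        raise DomainError(f"mean depth must be > 0, got {mean_depth_m}")
    if mean_depth_m <= params.depth_threshold:
        return params.shallow, "shallow"
    return params.combined, "combined"


def _resolve_preset(
    lake: WaterBody, params: OecdParameters, force_preset: "str | None"
) -> tuple[OecdPreset, str]:
    if force_preset is not None:
        return params.preset(force_preset), force_preset
    return select_parameters(lake.mean_depth_m, params)


def lake_concentration(
    load_kg_yr: float,
    discharge_m3_yr: float,
    lake: WaterBody,
    params: OecdParameters,
    force_preset: "str | None" = None,
) -> LakePrediction:
    """Predict the in-lake TP concentration for an annual load and outflow."""
    if load_kg_yr < 0:
        raise DomainError(f"load must be >= 0, got {load_kg_yr}")
    if discharge_m3_yr <= 0:
        raise NoFlushingError(
            f"{lake.waterbody_id}: outflow discharge must be > 0 to predict a "
            f"lake concentration (got {discharge_m3_yr})"
        )
    preset, name = _resolve_preset(lake, params, force_preset)
    tau = residence_time(lake.volume, discharge_m3_yr)
    tp_in = load_kg_yr / discharge_m3_yr * _KG_PER_M3_TO_UG_PER_L
    x = tp_in / (1.0 + math.sqrt(tau))
    tp_lake = preset.a * x**preset.b
    return LakePrediction(
        tp_inflow=tp_in,
        inflow_term=x,
        tp_lake=tp_lake,
        residence_time_yr=tau,
        preset_name=name,
    )


def load_for_concentration(
    target_ug_l: float,
    discharge_m3_yr: float,
    lake: WaterBody,
    params: OecdParameters,
    force_preset: "str | None" = None,
) -> float:
    """Annual load (kg P/yr) that would sustain a target lake concentration.

    Exact inverse of :func:`lake_concentration`:
    X = (TP_lake/a)**(1/b); TP_in = X*(1+sqrt(tau)); L = TP_in*Q/1e6.
    """
    if target_ug_l < 0:
        raise DomainError(f"target concentration must be >= 0, got {target_ug_l}")
    if discharge_m3_yr <= 0:
        raise NoFlushingError(
            f"{lake.waterbody_id}: outflow discharge must be > 0"
        )
    preset, _ = _resolve_preset(lake, params, force_preset)
    tau = residence_time(lake.volume, discharge_m3_yr)
    x = (target_ug_l / preset.a) ** (1.0 / preset.b)
    tp_in = x * (1.0 + math.sqrt(tau))
    return tp_in * discharge_m3_yr / _KG_PER_M3_TO_UG_PER_L


def scale_concentration(
    calibration: tuple[float, float], load_kg_yr: float, b: float
) -> float:
    """Concentration at a new load, scaled from a calibrated (L0, C0) pair.

    At fixed discharge and residence time the model gives C = C0*(L/L0)**b.
    Useful for what-if recalculations where only the load changes.
    """
    l0, c0 = calibration
    if not (l0 > 0 and c0 > 0):
        raise DomainError(f"calibration pair must be positive, got {calibration}")
    if load_kg_yr < 0:
        raise DomainError(f"load must be >= 0, got {load_kg_yr}")
    if not 0 < b <= 1:
        raise DomainError(f"exponent b must be in (0, 1], got {b}")
    return c0 * (load_kg_yr / l0) ** b
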