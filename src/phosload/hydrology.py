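"""Annual water balance: runoff, discharge and lake residence time.

The balance is deliberately simple and annual: actual evapotranspiration
is potential evapotranspiration capped at precipitation, runoff is the
remainder, and discharge is runoff over the catchment area.  Potential
evapotranspiration is a required input (mm/yr); an optional per-catchment
``runoff_coeff`` multiplier lets users emulate soil-hydrology effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_types import DomainError

__all__ = ["HydrologyResult", "annual_runoff", "discharge", "residence_time", "NO_FLUSHING"]

#: Sentinel residence time for a lake with zero outflow.
NO_FLUSHING = math.inf


@dataclass(frozen=True)
class HydrologyResult:
    """Per-catchment water balance outputs."""

    runoff_mm: float           # mm/yr over the catchment
    discharge_m3_yr: float     # local discharge generated in this catchment
    outflow_m3_yr: float       # accumulated discharge leaving the catchment
    residence_time_yr: float | None = None  # lake residence time; None if no lake


def annual_runoff(precip_mm: float, pet_mm: float, runoff_coeff: float = 1.0) -> float:
    """Annual runoff depth (mm/yr): max(0, precip - aet), aet = min(precip, pet)."""
    if precip_mm < 0 or pet_mm < 0:
        raise DomainError("precipitation and PET must be >= 0")
    if runoff_coeff < 0:
        raise DomainError("runoff_coeff must be >= 0")
    aet = min(precip_mm, pet_mm)
    return max(0.0, precip_mm - aet) * runoff_coeff


def discharge(runoff_mm: float, area_ha: float) -> float:
    """Discharge volume (m3/yr) from a runoff depth over an area.

    1 mm over 1 ha = 10 m3, so Q = runoff_mm / 1000 * area_ha * 1e4.
    """
    if runoff_mm < 0 or area_ha < 0:
        raise DomainError("runoff and area must be >= 0")
    return runoff_mm / 1000.0 * area_ha * 1.0e4


def residence_time(volume_m3: float, outflow_m3_yr: float) -> float:
    """Lake residence time tau = V / Q in years.

    Zero outflow yields the ``NO_FLUSHING`` sentinel (+inf) rather than an
    error, so callers can decide how to treat unflushed basins.
    """
    if not volume_m3 > 0:
        raise DomainError(f"lake volume must be > 0, got {volume_m3}")
    if outflow_m3_yr < 0:
        raise DomainError("outflow must be >= 0")
    if outflow_m3_yr == 0:
        return NO_FLUSHING
    return volume_m3 / outflow_m3_yr
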