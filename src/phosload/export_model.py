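"""Annual TP loads for a single sub-catchment.

Diffuse land loads are parcel area times the export coefficient for the
parcel's land-cover category and slope band.  Point/population sources are
per-capita rates for the sewered (urban) and riparian septic populations,
plus any explicitly quantified extra sources (fish farms, roosting birds,
atmospheric deposition, ...).  A ``wwtw_override`` extra source replaces
the per-capita urban term, for catchments where actual effluent routing is
known.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .core_types import (
    DomainError,
    ExportCoefficientTable,
    ExtraSource,
    Parcel,
    PerCapitaRates,
    SlopeClass,
    SourceApportionment,
    SubCatchment,
)

__all__ = [
    "classify_slope",
    "land_load",
    "population_loads",
    "extra_source_load",
    "local_sources",
]


def classify_slope(slope_degrees: float) -> SlopeClass:
    """Map a slope in degrees to its band: [0,4) Low, [4,13) Medium, [13,inf) High."""
    return SlopeClass.from_degrees(slope_degrees)


def land_load(
    parcels: Iterable[Parcel],
    ec_table: ExportCoefficientTable,
    setting: str = "median",
) -> float:
    """Total diffuse TP load (kg P/yr) from a list of land-cover parcels.

    ``setting`` selects the min/median/max coefficient column.
    """
    total = 0.0
    for p in parcels:
        total += p.area_ha * ec_table.coefficient(p.category, p.slope, setting)
    return total


def population_loads(
    urban_population: float,
    riparian_septic_population: float,
    rates: PerCapitaRates,
) -> tuple[float, float]:
    """(urban, septic) TP loads in kg P/yr from the two population terms."""
    if urban_population < 0 or riparian_septic_population < 0:
        raise DomainError("populations must be >= 0")
    return urban_population * rates.urban, riparian_septic_population * rates.septic


def extra_source_load(
    extra_sources: Sequence[ExtraSource],
) -> tuple[float, dict[str, float]]:
    """Sum of extra point-source loads and a per-type breakdown.

    ``wwtw_override`` entries are excluded here; they substitute for the
    urban per-capita term in :func:`local_sources`.
    """
    breakdown: dict[str, float] = {}
    for src in extra_sources:
        if src.source_type == "wwtw_override":
            continue
        breakdown[src.source_type] = breakdown.get(src.source_type, 0.0) + src.load_kg_yr
    return sum(breakdown.values()), breakdown


def wwtw_override_load(extra_sources: Sequence[ExtraSource]) -> "float | None":
    """Summed wwtw_override load, or None when no override is present."""
    overrides = [s.load_kg_yr for s in extra_sources if s.source_type == "wwtw_override"]
    if not overrides:
        return None
    return sum(overrides)


def local_sources(
    subcatchment: SubCatchment,
    ec_table: ExportCoefficientTable,
    rates: PerCapitaRates,
    setting: str = "median",
) -> SourceApportionment:
    """Apportioned local TP sources of one sub-catchment (no upstream term).

    Components: ``land``, ``urban``, ``septic`` and one entry per extra
    source type present.  When a ``wwtw_override`` extra source exists its
    load replaces the per-capita urban term.
    """
    land = land_load(subcatchment.parcels, ec_table, setting)
    urban, septic = population_loads(
        subcatchment.urban_population, subcatchment.riparian_septic_population, rates
    )
    override = wwtw_override_load(subcatchment.extra_sources)
    if override is not None:
        urban = override
    _, extras = extra_source_load(subcatchment.extra_sources)
    loads = {"land": land, "urban": urban, "septic": septic, **extras}
    return SourceApportionment(loads)
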