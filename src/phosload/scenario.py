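"""Scenario mode: perturb a network, re-run, and diff against baseline.

A scenario is a list of typed change records applied to a *copy* of the
network — land-cover transfers, extra-source additions/removals, climate
scaling, population changes — optionally combined with per-capita rate
overrides or a forced lake-model preset.  The original network is never
modified, so a baseline re-run after a scenario run reproduces baseline
outputs bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

from .core_types import (
    DomainError,
    ExtraSource,
    Parcel,
    PerCapitaRates,
    SubCatchmentNetwork,
    resolve_category,
    resolve_source_type,
)

__all__ = [
    "LandCoverTransfer",
    "AddExtraSource",
    "RemoveExtraSource",
    "ClimateScaling",
    "PopulationChange",
    "Scenario",
    "apply_scenario",
    "diff_report",
]


@dataclass(frozen=True)
class LandCoverTransfer:
    """Reassign ``area_ha`` from one land-cover category to another,
    preserving slope class.  Area is taken from the catchment's parcels of
    the source category in list order."""

    catchment_id: str
    from_category: str
    to_category: str
    area_ha: float


@dataclass(frozen=True)
class AddExtraSource:
    catchment_id: str
    source_type: str
    load_kg_yr: float


@dataclass(frozen=True)
class RemoveExtraSource:
    """Remove every extra source of the given type from the catchment."""

    catchment_id: str
    source_type: str


@dataclass(frozen=True)
class ClimateScaling:
    """Scale precipitation and/or PET; catchment_id None applies to all."""

    catchment_id: Optional[str] = None
    precip_factor: float = 1.0
    pet_factor: float = 1.0


@dataclass(frozen=True)
class PopulationChange:
    """Set new population values (None leaves a field unchanged)."""

    catchment_id: str
    urban_population: Optional[float] = None
    riparian_septic_population: Optional[float] = None


Change = Union[
    LandCoverTransfer, AddExtraSource, RemoveExtraSource, ClimateScaling, PopulationChange
]


@dataclass
class Scenario:
    """A named bundle of changes plus optional model-level overrides."""

    changes: list[Change] = field(default_factory=list)
    rates: Optional[PerCapitaRates] = None
    force_preset: Optional[str] = None
    name: str = "scenario"


def _require_catchment(network: SubCatchmentNetwork, cid: str):
    if cid not in network.nodes:
        raise DomainError(f"scenario references unknown catchment {cid!r}")
    return network.nodes[cid]


def _apply_transfer(network: SubCatchmentNetwork, ch: LandCoverTransfer) -> None:
    sc = _require_catchment(network, ch.catchment_id)
    if ch.area_ha < 0:
        raise DomainError("transfer area must be >= 0")
    src = resolve_category(ch.from_category)
    dst = resolve_category(ch.to_category)
    available = sum(p.area_ha for p in sc.parcels if p.category == src)
    if ch.area_ha > available * (1 + 1e-12) + 1e-12:
        raise DomainError(
            f"{ch.catchment_id}: cannot transfer {ch.area_ha} ha of {src!r}; "
            f"only {available} ha present"
        )
    remaining = ch.area_ha
    new_parcels: list[Parcel] = []
    for p in sc.parcels:
        if p.category == src and remaining > 0:
            take = min(p.area_ha, remaining)
            remaining -= take
            if p.area_ha - take > 1e-12:
                new_parcels.append(Parcel(src, p.slope, p.area_ha - take))
            if take > 0:
                new_parcels.append(Parcel(dst, p.slope, take))
        else:
            new_parcels.append(p)
    sc.parcels = new_parcels


def apply_scenario(
    network: SubCatchmentNetwork, changes: "Scenario | Sequence[Change]"
) -> SubCatchmentNetwork:
    """Apply change records to a deep copy of the network and return it."""
    if isinstance(changes, Scenario):
        changes = changes.changes
    out = network.copy()
    for ch in changes:
        if isinstance(ch, LandCoverTransfer):
            _apply_transfer(out, ch)
        elif isinstance(ch, AddExtraSource):
            sc = _require_catchment(out, ch.catchment_id)
            sc.extra_sources = list(sc.extra_sources) + [
                ExtraSource(ch.source_type, ch.load_kg_yr)
            ]
        elif isinstance(ch, RemoveExtraSource):
            sc = _require_catchment(out, ch.catchment_id)
            stype = resolve_source_type(ch.source_type)
            sc.extra_sources = [s for s in sc.extra_sources if s.source_type != stype]
        elif isinstance(ch, ClimateScaling):
            if ch.precip_factor < 0 or ch.pet_factor < 0:
                raise DomainError("climate scaling factors must be >= 0")
            targets = (
                [_require_catchment(out, ch.catchment_id)]
                if ch.catchment_id is not None
                else list(out.nodes.values())
            )
            for sc in targets:
                sc.precip_mm *= ch.precip_factor
                sc.pet_mm *= ch.pet_factor
        elif isinstance(ch, PopulationChange):
            sc = _require_catchment(out, ch.catchment_id)
            if ch.urban_population is not None:
                if ch.urban_population < 0:
                    raise DomainError("urban population must be >= 0")
                sc.urban_population = ch.urban_population
            if ch.riparian_septic_population is not None:
                if ch.riparian_septic_population < 0:
                    raise DomainError("riparian septic population must be >= 0")
                sc.riparian_septic_population = ch.riparian_septic_population
        else:
            raise DomainError(f"unknown change record: {ch!r}")
    out.validate()
    return out


_CHANGE_TYPES = {
    "land_cover_transfer": LandCoverTransfer,
    "add_extra_source": AddExtraSource,
    "remove_extra_source": RemoveExtraSource,
    "climate_scaling": ClimateScaling,
    "population_change": PopulationChange,
}


def load_scenario(path) -> Scenario:
    """Read a scenario from a YAML file.

    Layout: optional top-level ``name``, ``force_preset`` and ``rates``
    (``urban``/``septic``), plus ``changes`` — a list of mappings each
    carrying a ``type`` key (one of land_cover_transfer, add_extra_source,
    remove_extra_source, climate_scaling, population_change) and that
    record's fields.
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    changes: list[Change] = []
    for rec in doc.get("changes", []):
        rec = dict(rec)
        kind = rec.pop("type", None)
        if kind not in _CHANGE_TYPES:
            raise DomainError(
                f"unknown change type {kind!r}; expected one of {sorted(_CHANGE_TYPES)}"
            )
        changes.append(_CHANGE_TYPES[kind](**rec))
    rates = None
    if "rates" in doc:
        rates = PerCapitaRates(**doc["rates"])
    return Scenario(
        changes=changes,
        rates=rates,
        force_preset=doc.get("force_preset"),
        name=doc.get("name", "scenario"),
    )


def diff_report(baseline: pd.DataFrame, scenario: pd.DataFrame) -> pd.DataFrame:
    """Per-waterbody deltas between two results tables.

    Both inputs are results frames from the pipeline (indexed rows with
    ``waterbody_id``, ``total_load_kg_yr``, ``tp_lake_ug_l``,
    ``wfd_class`` columns).  Returns signed load/concentration deltas and
    the class transition (empty string when unchanged).
    """
    b = baseline.set_index("waterbody_id")
    s = scenario.set_index("waterbody_id")
    if set(b.index) != set(s.index):
        raise DomainError("baseline and scenario cover different waterbody sets")
    s = s.reindex(b.index)
    out = pd.DataFrame(index=b.index)
    out["load_delta_kg_yr"] = s["total_load_kg_yr"] - b["total_load_kg_yr"]
    out["conc_delta_ug_l"] = s["tp_lake_ug_l"] - b["tp_lake_ug_l"]
    transition = []
    for wid in b.index:
        before, after = b.loc[wid, "wfd_class"], s.loc[wid, "wfd_class"]
        transition.append("" if before == after else f"{before}->{after}")
    out["class_transition"] = transition
    return out.reset_index()
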