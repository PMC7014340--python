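"""CSV bundle readers/writers and the end-to-end pipeline.

A bundle directory holds ``catchments.csv``, ``parcels.csv``,
``lakes.csv``, ``breakpoints.csv`` and optionally ``extra_sources.csv``.
All files are UTF-8, comma-separated, header row required, empty string
for missing values.  Every type invariant is validated at load time and
violations are reported with file and line number.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .core_types import (
    ConfigurationError,
    ExportCoefficientTable,
    ExtraSource,
    OecdParameters,
    Parcel,
    PerCapitaRates,
    PhosloadError,
    SlopeClass,
    SubCatchment,
    SubCatchmentNetwork,
    WaterBody,
    WfdBreakpoints,
    load_defaults,
)
from .classification import headroom_load, traffic_light, trophic_class, wfd_status
from .routing import route

__all__ = ["BundleLoadError", "read_bundle", "write_bundle", "run_pipeline", "write_results"]


class BundleLoadError(PhosloadError, ValueError):
    """A bundle file is missing, malformed, or violates an invariant."""


def _read_csv(path: Path, required: set[str], optional: bool = False) -> Optional[pd.DataFrame]:
    if not path.exists():
        if optional:
            return None
        raise BundleLoadError(f"{path}: required file is missing")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - surface any parse failure with the path
        raise BundleLoadError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = required - set(df.columns)
    if missing:
        raise BundleLoadError(f"{path}: missing columns {sorted(missing)}")
    return df


def _num(value: str, default: float = 0.0) -> float:
    if value == "":
        return default
    return float(value)


def read_bundle(directory) -> tuple[SubCatchmentNetwork, dict[str, WfdBreakpoints]]:
    """Read a bundle directory into a validated network + breakpoint map."""
    d = Path(directory)
    catchments = _read_csv(
        d / "catchments.csv",
        {"catchment_id", "downstream_id", "land_area_ha", "urban_population",
         "riparian_septic_population", "precip_mm", "pet_mm"},
    )
    parcels = _read_csv(d / "parcels.csv", {"catchment_id", "landcover", "area_ha"})
    if "slope_degrees" not in parcels.columns and "slope_class" not in parcels.columns:
        raise BundleLoadError(
            f"{d / 'parcels.csv'}: need a slope_degrees or slope_class column"
        )
    lakes = _read_csv(
        d / "lakes.csv", {"waterbody_id", "catchment_id", "surface_area_km2", "mean_depth_m"}
    )
    breaks = _read_csv(d / "breakpoints.csv", {"waterbody_id", "hg", "gm", "mp", "pb"})
    extras = _read_csv(
        d / "extra_sources.csv", {"catchment_id", "source_type", "load_kg_yr"}, optional=True
    )

    def fail(path: Path, row: int, exc: Exception):
        # +2: header line and 1-based numbering
        raise BundleLoadError(f"{path}:{row + 2}: {exc}") from exc

    parcel_map: dict[str, list[Parcel]] = {}
    ppath = d / "parcels.csv"
    for i, row in enumerate(parcels.itertuples(index=False)):
        try:
            slope = (
                SlopeClass.coerce(row.slope_class)
                if "slope_class" in parcels.columns and row.slope_class != ""
                else SlopeClass.from_degrees(float(row.slope_degrees))
            )
            parcel_map.setdefault(row.catchment_id, []).append(
                Parcel(row.landcover, slope, float(row.area_ha))
            )
        except (PhosloadError, ValueError) as exc:
            fail(ppath, i, exc)

    extra_map: dict[str, list[ExtraSource]] = {}
    if extras is not None:
        epath = d / "extra_sources.csv"
        for i, row in enumerate(extras.itertuples(index=False)):
            try:
                extra_map.setdefault(row.catchment_id, []).append(
                    ExtraSource(row.source_type, float(row.load_kg_yr))
                )
            except (PhosloadError, ValueError) as exc:
                fail(epath, i, exc)

    lake_map: dict[str, WaterBody] = {}
    lpath = d / "lakes.csv"
    for i, row in enumerate(lakes.itertuples(index=False)):
        try:
            volume = None
            if "volume_m3" in lakes.columns and row.volume_m3 != "":
                volume = float(row.volume_m3)
            if row.catchment_id in lake_map:
                raise ConfigurationError(
                    f"catchment {row.catchment_id!r} has more than one lake"
                )
            lake_map[row.catchment_id] = WaterBody(
                row.waterbody_id, float(row.surface_area_km2), float(row.mean_depth_m), volume
            )
        except (PhosloadError, ValueError) as exc:
            fail(lpath, i, exc)

    nodes: dict[str, SubCatchment] = {}
    cpath = d / "catchments.csv"
    for i, row in enumerate(catchments.itertuples(index=False)):
        try:
            nodes[row.catchment_id] = SubCatchment(
                catchment_id=row.catchment_id,
                downstream_id=row.downstream_id or None,
                land_area_ha=float(row.land_area_ha),
                parcels=parcel_map.get(row.catchment_id, []),
                urban_population=_num(row.urban_population),
                riparian_septic_population=_num(row.riparian_septic_population),
                extra_sources=extra_map.get(row.catchment_id, []),
                precip_mm=_num(row.precip_mm),
                pet_mm=_num(row.pet_mm),
                runoff_coeff=_num(getattr(row, "runoff_coeff", ""), 1.0)
                if "runoff_coeff" in catchments.columns else 1.0,
                lake=lake_map.get(row.catchment_id),
            )
        except (PhosloadError, ValueError) as exc:
            fail(cpath, i, exc)

    try:
        network = SubCatchmentNetwork(nodes)
    except PhosloadError as exc:
        raise BundleLoadError(f"{cpath}: {exc}") from exc

    bp_map: dict[str, WfdBreakpoints] = {}
    bpath = d / "breakpoints.csv"
    for i, row in enumerate(breaks.itertuples(index=False)):
        try:
            bp_map[row.waterbody_id] = WfdBreakpoints(
                row.waterbody_id, float(row.hg), float(row.gm), float(row.mp), float(row.pb)
            )
        except (PhosloadError, ValueError) as exc:
            fail(bpath, i, exc)

    return network, bp_map


def write_bundle(
    network: SubCatchmentNetwork,
    breakpoints: Mapping[str, WfdBreakpoints],
    directory,
) -> None:
    """Write a network + breakpoints back out as a bundle directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    order = sorted(network.nodes)

    pd.DataFrame(
        [
            {
                "catchment_id": cid,
                "downstream_id": network.nodes[cid].downstream_id or "",
                "land_area_ha": network.nodes[cid].land_area_ha,
                "urban_population": network.nodes[cid].urban_population,
                "riparian_septic_population": network.nodes[cid].riparian_septic_population,
                "precip_mm": network.nodes[cid].precip_mm,
                "pet_mm": network.nodes[cid].pet_mm,
                "runoff_coeff": network.nodes[cid].runoff_coeff,
            }
            for cid in order
        ]
    ).to_csv(d / "catchments.csv", index=False)

    pd.DataFrame(
        [
            {"catchment_id": cid, "landcover": p.category,
             "slope_class": p.slope.value, "area_ha": p.area_ha}
            for cid in order
            for p in network.nodes[cid].parcels
        ],
        columns=["catchment_id", "landcover", "slope_class", "area_ha"],
    ).to_csv(d / "parcels.csv", index=False)

    pd.DataFrame(
        [
            {"waterbody_id": sc.lake.waterbody_id, "catchment_id": cid,
             "surface_area_km2": sc.lake.surface_area_km2,
             "mean_depth_m": sc.lake.mean_depth_m,
             "volume_m3": "" if sc.lake.volume_m3 is None else sc.lake.volume_m3}
            for cid in order
            for sc in [network.nodes[cid]]
            if sc.lake is not None
        ],
        columns=["waterbody_id", "catchment_id", "surface_area_km2", "mean_depth_m", "volume_m3"],
    ).to_csv(d / "lakes.csv", index=False)

    pd.DataFrame(
        [
            {"waterbody_id": wid, "hg": bp.hg, "gm": bp.gm, "mp": bp.mp, "pb": bp.pb}
            for wid, bp in sorted(breakpoints.items())
        ],
        columns=["waterbody_id", "hg", "gm", "mp", "pb"],
    ).to_csv(d / "breakpoints.csv", index=False)

    extra_rows = [
        {"catchment_id": cid, "source_type": s.source_type, "load_kg_yr": s.load_kg_yr}
        for cid in order
        for s in network.nodes[cid].extra_sources
    ]
    if extra_rows:
        pd.DataFrame(extra_rows).to_csv(d / "extra_sources.csv", index=False)


def run_pipeline(
    network: SubCatchmentNetwork,
    breakpoints: Mapping[str, WfdBreakpoints],
    ec_table: Optional[ExportCoefficientTable] = None,
    rates: Optional[PerCapitaRates] = None,
    params: Optional[OecdParameters] = None,
    *,
    setting: str = "median",
    retention_mode: str = "all_lakes",
    force_preset: "str | None" = None,
    discharge_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Run the cascade and classify every waterbody.

    Returns one row per standing water, sorted by waterbody_id, with load
    apportionment, outflow, predicted concentration, WFD class, trophic
    class, traffic light and remaining headroom.  Deterministic for fixed
    inputs.
    """
    if ec_table is None or rates is None or params is None:
        d_table, d_rates, d_params = load_defaults()
        ec_table = ec_table or d_table
        rates = rates or d_rates
        params = params or d_params

    results = route(
        network, ec_table, rates, params,
        setting=setting, retention_mode=retention_mode,
        force_preset=force_preset, discharge_multiplier=discharge_multiplier,
    )

    rows = []
    for cid in sorted(network.nodes):
        sc = network.nodes[cid]
        if sc.lake is None:
            continue
        res = results[cid]
        loads = res.apportionment.loads
        extras = sum(
            v for k, v in loads.items() if k not in ("land", "urban", "septic", "upstream")
        )
        row: dict[str, object] = {
            "waterbody_id": sc.lake.waterbody_id,
            "catchment_id": cid,
            "load_land_kg_yr": loads.get("land", 0.0),
            "load_urban_kg_yr": loads.get("urban", 0.0),
            "load_septic_kg_yr": loads.get("septic", 0.0),
            "load_extra_kg_yr": extras,
            "load_upstream_kg_yr": loads.get("upstream", 0.0),
            "total_load_kg_yr": res.apportionment.total,
            "outflow_m3_yr": res.hydrology.outflow_m3_yr,
            "residence_time_yr": res.hydrology.residence_time_yr,
            "tp_lake_ug_l": res.lake.tp_lake if res.lake is not None else math.nan,
            "oecd_preset": res.lake.preset_name if res.lake is not None else "",
        }
        bp = breakpoints.get(sc.lake.waterbody_id)
        if res.lake is not None and bp is not None:
            conc = res.lake.tp_lake
            hr = headroom_load(
                res.apportionment.total, res.hydrology.outflow_m3_yr, sc.lake, bp,
                params, force_preset,
            )
            row.update(
                wfd_class=wfd_status(conc, bp).label,
                trophic=trophic_class(conc).value,
                traffic_light=traffic_light(conc, bp).value,
                headroom_kg_yr=hr.load_kg_yr,
                boundary_exceeded=hr.boundary_exceeded,
            )
        else:
            row.update(
                wfd_class="",
                trophic=trophic_class(row["tp_lake_ug_l"]).value
                if res.lake is not None else "",
                traffic_light="", headroom_kg_yr=math.nan, boundary_exceeded=False,
            )
        rows.append(row)

    columns = [
        "waterbody_id", "catchment_id", "load_land_kg_yr", "load_urban_kg_yr",
        "load_septic_kg_yr", "load_extra_kg_yr", "load_upstream_kg_yr",
        "total_load_kg_yr", "outflow_m3_yr", "residence_time_yr", "tp_lake_ug_l",
        "oecd_preset", "wfd_class", "trophic", "traffic_light", "headroom_kg_yr",
        "boundary_exceeded",
    ]
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values("waterbody_id", kind="stable").reset_index(drop=True)


def write_results(df: pd.DataFrame, path) -> None:
    """Write a results table with fixed formatting (loads and
    concentrations to 1 decimal place) for byte-stable output."""
    out = df.copy()
    for col in out.columns:
        if col.endswith("_kg_yr") or col == "tp_lake_ug_l":
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
        elif col in ("outflow_m3_yr", "residence_time_yr"):
            out[col] = out[col].map(lambda v: "" if v is None or pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, index=False)
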