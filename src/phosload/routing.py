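"""Cascade loads and discharge through the sub-catchment network.

Each sub-catchment exports its local sources plus whatever arrives from
immediately upstream neighbours; discharge accumulates the same way.  At
a node with a standing water the OECD model converts the accumulated load
into an in-lake concentration, and — when retention applies — the load
passed downstream becomes TP_lake * outflow (the lake traps the rest).

``retention_mode`` controls where retention applies: ``all_lakes``
(default; every lake traps P before passing it on) or ``terminal_only``
(only outlet lakes, upstream lakes are treated as pass-through).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .core_types import (
    DomainError,
    ExportCoefficientTable,
    NetworkError,
    OecdParameters,
    PerCapitaRates,
    SourceApportionment,
    SubCatchmentNetwork,
)
from .export_model import local_sources
from .hydrology import HydrologyResult, annual_runoff, discharge
from .lake_model import LakePrediction, lake_concentration

__all__ = ["RoutedResult", "topological_order", "route"]

RETENTION_MODES = ("all_lakes", "terminal_only")


@dataclass
class RoutedResult:
    """Everything the cascade computes for one sub-catchment."""

    apportionment: SourceApportionment   # local components + 'upstream'
    hydrology: HydrologyResult
    lake: Optional[LakePrediction]
    exported_load_kg_yr: float           # load passed to the downstream node


def _graph(network: SubCatchmentNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    for cid, sc in network.nodes.items():
        if sc.downstream_id is not None:
            g.add_edge(cid, sc.downstream_id)
    return g


def topological_order(network: SubCatchmentNetwork) -> list[str]:
    """Node ids ordered so every node appears after all its upstream nodes.

    Ties are broken by id so the order is deterministic.
    """
    g = _graph(network)
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        edge = nx.find_cycle(g)[0]
        raise NetworkError(f"cycle detected at edge {edge[0]!r} -> {edge[1]!r}") from None


def route(
    network: SubCatchmentNetwork,
    ec_table: ExportCoefficientTable,
    rates: PerCapitaRates,
    params: OecdParameters,
    setting: str = "median",
    retention_mode: str = "all_lakes",
    force_preset: "str | None" = None,
    discharge_multiplier: float = 1.0,
) -> dict[str, RoutedResult]:
    """Run the full cascade and return per-catchment results.

    ``discharge_multiplier`` scales every local discharge uniformly; it
    exists for discharge sensitivity analysis and scenario work.
    """
    if retention_mode not in RETENTION_MODES:
        raise DomainError(f"retention_mode must be one of {RETENTION_MODES}")
    if not discharge_multiplier > 0:
        raise DomainError("discharge_multiplier must be > 0")

    order = topological_order(network)
    results: dict[str, RoutedResult] = {}

    for cid in order:
        sc = network.nodes[cid]
        runoff = annual_runoff(sc.precip_mm, sc.pet_mm, sc.runoff_coeff)
        local_q = discharge(runoff, sc.land_area_ha) * discharge_multiplier

        inflow_load = 0.0
        inflow_q = 0.0
        for up in network.upstream_ids(cid):
            inflow_load += results[up].exported_load_kg_yr
            inflow_q += results[up].hydrology.outflow_m3_yr
        outflow_q = local_q + inflow_q

        local = local_sources(sc, ec_table, rates, setting)
        apportionment = local.merged(upstream=inflow_load)
        total_load = apportionment.total

        prediction: Optional[LakePrediction] = None
        retain = sc.lake is not None and (
            retention_mode == "all_lakes" or sc.downstream_id is None
        )
        if sc.lake is not None and outflow_q > 0:
            prediction = lake_concentration(
                total_load, outflow_q, sc.lake, params, force_preset
            )
        if retain and prediction is not None:
            exported = prediction.tp_lake * outflow_q / 1.0e6
        else:
            exported = total_load

        tau = prediction.residence_time_yr if prediction is not None else None
        results[cid] = RoutedResult(
            apportionment=apportionment,
            hydrology=HydrologyResult(
                runoff_mm=runoff,
                discharge_m3_yr=local_q,
                outflow_m3_yr=outflow_q,
                residence_time_yr=tau,
            ),
            lake=prediction,
            exported_load_kg_yr=exported,
        )
    return results
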