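"""One-at-a-time sensitivity drivers.

Three procedures: rerun with each export-coefficient column (min, median,
max); rerun with the discharge scaled +/-10% in 5% steps; and a generic
one-parameter-at-a-time driver that perturbs one named input over a grid
while holding everything else constant and ranks parameters by their
largest effect on the mean lake concentration.

Summary statistics use linear interpolation between order statistics for
percentiles, the n-1 denominator for the standard deviation, and
SE = SD/sqrt(n).
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_types import (
    ConfigurationError,
    DomainError,
    ExportCoefficientTable,
    OecdParameters,
    OecdPreset,
    PerCapitaRates,
    SubCatchmentNetwork,
    WfdBreakpoints,
    load_defaults,
)
from .io import run_pipeline
from .scenario import ClimateScaling, apply_scenario

__all__ = ["ec_sensitivity", "discharge_sensitivity", "one_at_a_time", "summary_statistics"]

_SUMMARY_ROWS = (
    "Minimum", "5th percentile", "10th percentile", "Median", "Mean",
    "90th percentile", "95th percentile", "Maximum",
    "Standard Deviation", "Standard Error",
)


def summary_statistics(values: Sequence[float]) -> pd.Series:
    """The distribution summary used by the sensitivity report tables."""
    x = np.asarray(list(values), dtype=float)
    n = len(x)
    if n == 0:
        return pd.Series({row: math.nan for row in _SUMMARY_ROWS})
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    return pd.Series(
        {
            "Minimum": float(np.min(x)),
            "5th percentile": float(np.percentile(x, 5)),
            "10th percentile": float(np.percentile(x, 10)),
            "Median": float(np.median(x)),
            "Mean": float(np.mean(x)),
            "90th percentile": float(np.percentile(x, 90)),
            "95th percentile": float(np.percentile(x, 95)),
            "Maximum": float(np.max(x)),
            "Standard Deviation": sd,
            "Standard Error": sd / math.sqrt(n),
        }
    )


def _defaults(ec_table, rates, params):
    if ec_table is None or rates is None or params is None:
        d_table, d_rates, d_params = load_defaults()
        ec_table = ec_table or d_table
        rates = rates or d_rates
        params = params or d_params
    return ec_table, rates, params


def ec_sensitivity(
    network: SubCatchmentNetwork,
    breakpoints: Mapping[str, WfdBreakpoints],
    ec_table: Optional[ExportCoefficientTable] = None,
    rates: Optional[PerCapitaRates] = None,
    params: Optional[OecdParameters] = None,
    **run_kwargs,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Full reruns under the min, median and max export-coefficient sets.

    Returns the three per-waterbody results tables and a summary frame
    with the lowest, mean and highest concentration per setting plus each
    setting's ratio to the median run (percent).
    """
    ec_table, rates, params = _defaults(ec_table, rates, params)
    for (cat, slope), rng in ec_table.entries.items():
        if rng.min is None or rng.max is None:  # pragma: no cover - ECRange forbids
            raise ConfigurationError(f"no min/max range for ({cat}, {slope})")

    runs = {
        setting: run_pipeline(
            network, breakpoints, ec_table, rates, params, setting=setting, **run_kwargs
        )
        for setting in ("min", "median", "max")
    }
    stats = {
        setting: {
            "Lowest TP": float(df["tp_lake_ug_l"].min()),
            "Mean TP": float(df["tp_lake_ug_l"].mean()),
            "Highest TP": float(df["tp_lake_ug_l"].max()),
        }
        for setting, df in runs.items()
    }
    summary = pd.DataFrame(stats)[["min", "median", "max"]]
    for setting in ("min", "max"):
        summary[f"{setting}_vs_median_percent"] = (
            100.0 * summary[setting] / summary["median"]
        )
    return runs, summary


def discharge_sensitivity(
    network: SubCatchmentNetwork,
    breakpoints: Mapping[str, WfdBreakpoints],
    multipliers: Sequence[float] = (0.90, 0.95, 1.05, 1.10),
    ec_table: Optional[ExportCoefficientTable] = None,
    rates: Optional[PerCapitaRates] = None,
    params: Optional[OecdParameters] = None,
    **run_kwargs,
) -> pd.DataFrame:
    """Full reruns with every discharge scaled by each multiplier.

    Returns a summary table: one column per multiplier (baseline 1.0
    first) and the distribution statistics of the lake concentrations as
    rows.
    """
    if any(m <= 0 for m in multipliers):
        raise DomainError("discharge multipliers must be > 0")
    ec_table, rates, params = _defaults(ec_table, rates, params)
    def stats(m: float) -> pd.Series:
        df = run_pipeline(
            network, breakpoints, ec_table, rates, params,
            discharge_multiplier=m, **run_kwargs,
        )
        return summary_statistics(df["tp_lake_ug_l"].dropna())

    columns = {"baseline": stats(1.0)}
    for m in multipliers:
        columns[f"x{m:g}"] = stats(m)
    return pd.DataFrame(columns)


#: Parameters understood by :func:`one_at_a_time` and how each enters.
OAT_PARAMETERS = (
    "ec_setting", "urban_rate", "septic_rate", "discharge_multiplier",
    "precip_factor", "pet_factor", "depth_threshold",
)


def one_at_a_time(
    network: SubCatchmentNetwork,
    breakpoints: Mapping[str, WfdBreakpoints],
    grid: Mapping[str, Sequence],
    ec_table: Optional[ExportCoefficientTable] = None,
    rates: Optional[PerCapitaRates] = None,
    params: Optional[OecdParameters] = None,
    **run_kwargs,
) -> pd.DataFrame:
    """Perturb each named parameter over its grid, one at a time.

    The effect size of a parameter is the maximum absolute relative
    change of the mean lake concentration across its grid, against the
    all-defaults baseline.  Returns a frame ranked by descending effect.
    """
    ec_table, rates, params = _defaults(ec_table, rates, params)
    for name in grid:
        if name not in OAT_PARAMETERS:
            raise DomainError(
                f"unknown parameter {name!r}; expected one of {OAT_PARAMETERS}"
            )

    def mean_conc(**overrides) -> float:
        net = overrides.pop("network", network)
        df = run_pipeline(
            net, breakpoints,
            overrides.pop("ec_table", ec_table),
            overrides.pop("rates", rates),
            overrides.pop("params", params),
            **{**run_kwargs, **overrides},
        )
        return float(df["tp_lake_ug_l"].mean())

    baseline = mean_conc()
    rows = []
    for name, values in grid.items():
        worst = 0.0
        for v in values:
            if name == "ec_setting":
                m = mean_conc(setting=v)
            elif name == "urban_rate":
                m = mean_conc(rates=PerCapitaRates(urban=float(v), septic=rates.septic))
            elif name == "septic_rate":
                m = mean_conc(rates=PerCapitaRates(urban=rates.urban, septic=float(v)))
            elif name == "discharge_multiplier":
                m = mean_conc(discharge_multiplier=float(v))
            elif name == "precip_factor":
                net = apply_scenario(network, [ClimateScaling(precip_factor=float(v))])
                m = mean_conc(network=net)
            elif name == "pet_factor":
                net = apply_scenario(network, [ClimateScaling(pet_factor=float(v))])
                m = mean_conc(network=net)
            elif name == "depth_threshold":
                p = OecdParameters(params.shallow, params.combined, float(v))
                m = mean_conc(params=p)
            if baseline != 0:
                worst = max(worst, abs(m - baseline) / abs(baseline))
        rows.append({"parameter": name, "max_abs_relative_change": worst})
    df = pd.DataFrame(rows, columns=["parameter", "max_abs_relative_change"])
    return df.sort_values(
        "max_abs_relative_change", ascending=False, kind="stable"
    ).reset_index(drop=True)
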