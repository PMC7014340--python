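"""Shared domain types, default constants and configuration.

The central objects are the export-coefficient table (land cover x slope
-> kg P/ha/yr), the per-capita waste-water rates, the OECD lake-model
parameter presets, and the sub-catchment network that everything else
operates on.  All types validate their invariants eagerly so that bad
input data fails at load time with a useful message rather than deep
inside a model run.
"""

from __future__ import annotations

import copy
import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PhosloadError(Exception):
    """Base class for all package errors."""


class DomainError(PhosloadError, ValueError):
    """An argument is outside its physical domain (negative area, ...)."""


class ConfigurationError(PhosloadError, ValueError):
    """A packaged or user-supplied table violates its invariants."""


class CategoryLookupError(PhosloadError, KeyError):
    """A land-cover category name is not in the registry."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"unknown land-cover category: {name!r}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep message plain
        return self.args[0]


class NetworkError(PhosloadError, ValueError):
    """The sub-catchment network is not a forest of trees toward outlets."""


class NoFlushingError(PhosloadError, ValueError):
    """A lake concentration was requested with zero outflow discharge."""


# ---------------------------------------------------------------------------
# Slope classes
# ---------------------------------------------------------------------------

class SlopeClass(enum.Enum):
    """Slope bands used by the export-coefficient table.

    Intervals are half-open and lower-inclusive: Low [0, 4) degrees,
    Medium [4, 13), High [13, inf).
    """

    LOW = "Low"
    MEDIUM = "Medium"
    HIGH = "High"

    @classmethod
    def from_degrees(cls, slope_degrees: float) -> "SlopeClass":
        if not math.isfinite(slope_degrees) or slope_degrees < 0:
            raise DomainError(f"slope must be a finite value >= 0, got {slope_degrees}")
        if slope_degrees < 4.0:
            return cls.LOW
        if slope_degrees < 13.0:
            return cls.MEDIUM
        return cls.HIGH

    @classmethod
    def coerce(cls, value: "SlopeClass | str | float") -> "SlopeClass":
        """Accept a SlopeClass, a class name ('Low'), or slope in degrees."""
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            try:
                return cls(value.capitalize())
            except ValueError:
                raise DomainError(f"unknown slope class: {value!r}") from None
        return cls.from_degrees(float(value))


#: Boundaries of the slope bands, degrees.
SLOPE_BOUNDARIES_DEGREES = (0.0, 4.0, 13.0)


# ---------------------------------------------------------------------------
# Land-cover registry
# ---------------------------------------------------------------------------

#: Canonical land-cover categories of the export-coefficient table.  Rows
#: that aggregate several mapped classes keep the full comma-separated name;
#: each component resolves to its row through the alias map below.
LAND_COVER_CATEGORIES: tuple[str, ...] = (
    "Water",
    "Wetland",
    "Blanket bog & peatland",
    "Arable",
    "Improved grassland",
    "Coarse grassland, Smooth grassland, Heather all types, Bracken",
    "Cliffs",
    "Montane vegetation",
    "Low scrub",
    "Broadleaved woodland",
    "Mixed woodland, Open canopy young plantation",
    "Coniferous plantation",
    "Recently ploughed land",
    "Woodland recently felled",
    "Ripping",
    "Estuary, Salt marsh, Dune land, Maritime grasslands & heaths",
    "Airfields, Recreational land, Quarries, Other land, Road & rail",
    "Factories & urban",
)

def _build_aliases() -> dict[str, str]:
    aliases: dict[str, str] = {}
    for cat in LAND_COVER_CATEGORIES:
        aliases[cat.lower()] = cat
        for part in cat.split(","):
            aliases.setdefault(part.strip().lower(), cat)
    # common shorthand seen in field datasets
    aliases["heather"] = aliases["heather all types"]
    aliases["coarse grassland"] = aliases["coarse grassland"]
    aliases["blanket bog"] = aliases["blanket bog & peatland"]
    aliases["peatland"] = aliases["blanket bog & peatland"]
    aliases["urban"] = aliases["factories & urban"]
    return aliases

_CATEGORY_ALIASES = _build_aliases()


def resolve_category(name: str) -> str:
    """Resolve a land-cover name (or a component of an aggregate row) to
    its canonical registry entry; unknown names raise CategoryLookupError."""
    key = str(name).strip().lower()
    try:
        return _CATEGORY_ALIASES[key]
    except KeyError:
        raise CategoryLookupError(name) from None


# ---------------------------------------------------------------------------
# Export-coefficient table
# ---------------------------------------------------------------------------

EC_SETTINGS = ("min", "median", "max")


@dataclass(frozen=True)
class ECRange:
    """min/median/max TP export coefficients, kg P/ha/yr."""

    min: float
    median: float
    max: float

    def __post_init__(self):
        if not (0.0 <= self.min <= self.median <= self.max):
            raise ConfigurationError(
                f"export coefficients must satisfy 0 <= min <= median <= max, "
                f"got ({self.min}, {self.median}, {self.max})"
            )

    def get(self, setting: str) -> float:
        if setting not in EC_SETTINGS:
            raise DomainError(f"setting must be one of {EC_SETTINGS}, got {setting!r}")
        return getattr(self, setting)


@dataclass
class ExportCoefficientTable:
    """Land-cover x slope-class lookup of TP export coefficients."""

    entries: dict[tuple[str, SlopeClass], ECRange]

    def __post_init__(self):
        for (cat, slope), rng in self.entries.items():
            if cat not in LAND_COVER_CATEGORIES:
                raise CategoryLookupError(cat)
            if not isinstance(slope, SlopeClass):
                raise ConfigurationError(f"bad slope key {slope!r} for {cat!r}")
            if not isinstance(rng, ECRange):
                raise ConfigurationError(f"bad entry for ({cat!r}, {slope})")

    def range_for(self, category: str, slope: "SlopeClass | str | float") -> ECRange:
        cat = resolve_category(category)
        sl = SlopeClass.coerce(slope)
        try:
            return self.entries[(cat, sl)]
        except KeyError:
            raise ConfigurationError(f"no export coefficient for ({cat!r}, {sl})") from None

    def coefficient(self, category: str, slope, setting: str = "median") -> float:
        return self.range_for(category, slope).get(setting)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExportCoefficientTable":
        required = {"category", "slope_class", "ec_min", "ec_median", "ec_max"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"export-coefficient table missing columns: {sorted(missing)}")
        entries: dict[tuple[str, SlopeClass], ECRange] = {}
        for row in df.itertuples(index=False):
            cat = resolve_category(row.category)
            slope = SlopeClass.coerce(row.slope_class)
            entries[(cat, slope)] = ECRange(float(row.ec_min), float(row.ec_median), float(row.ec_max))
        return cls(entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": cat, "slope_class": slope.value,
             "ec_min": rng.min, "ec_median": rng.median, "ec_max": rng.max}
            for (cat, slope), rng in sorted(
                self.entries.items(),
                key=lambda kv: (LAND_COVER_CATEGORIES.index(kv[0][0]), kv[0][1].value),
            )
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_csv(cls, path) -> "ExportCoefficientTable":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def copy(self) -> "ExportCoefficientTable":
        return ExportCoefficientTable(dict(self.entries))


# ---------------------------------------------------------------------------
# Per-capita rates and OECD parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerCapitaRates:
    """Annual per-capita TP loads to water, kg P/person/yr.

    ``urban`` is the waste-water-treatment-works (sewered) rate applied to
    the urban population; ``septic`` applies to the riparian population on
    septic tanks.
    """

    urban: float = 0.9125
    septic: float = 0.25

    def __post_init__(self):
        if self.urban < 0 or self.septic < 0:
            raise DomainError("per-capita rates must be >= 0")


@dataclass(frozen=True)
class OecdPreset:
    """One (a, b) pair of the empirical lake model TP_lake = a * X**b."""

    a: float
    b: float

    def __post_init__(self):
        if not self.a > 0:
            raise ConfigurationError(f"multiplier a must be > 0, got {self.a}")
        if not 0 < self.b <= 1:
            raise ConfigurationError(f"exponent b must be in (0, 1], got {self.b}")


@dataclass(frozen=True)
class OecdParameters:
    """Parameterisation of the OECD load->concentration model.

    Two presets are carried: ``shallow`` (shallow lakes and reservoirs,
    a=1.02, b=0.88) and ``combined`` (full cross-lake dataset, a=1.55,
    b=0.82).  ``depth_threshold`` (m) governs which preset a waterbody
    gets: mean depth <= threshold -> shallow, deeper -> combined.
    """

    shallow: OecdPreset = OecdPreset(1.02, 0.88)
    combined: OecdPreset = OecdPreset(1.55, 0.82)
    depth_threshold: float = 3.0

    def __post_init__(self):
        if not self.depth_threshold > 0:
            raise ConfigurationError("depth_threshold must be > 0")

    def preset(self, name: str) -> OecdPreset:
        if name not in ("shallow", "combined"):
            raise DomainError(f"preset must be 'shallow' or 'combined', got {name!r}")
        return getattr(self, name)


# ---------------------------------------------------------------------------
# Waterbodies, sub-catchments, network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterBody:
    """Standing-water morphometry. Volume defaults to area x mean depth."""

    waterbody_id: str
    surface_area_km2: float
    mean_depth_m: float
    volume_m3: Optional[float] = None

    def __post_init__(self):
        if not self.surface_area_km2 > 0:
            raise DomainError(f"{self.waterbody_id}: surface area must be > 0")
        if not self.mean_depth_m > 0:
            raise DomainError(f"{self.waterbody_id}: mean depth must be > 0")
        if self.volume_m3 is not None and not self.volume_m3 > 0:
            raise DomainError(f"{self.waterbody_id}: volume must be > 0")

    @property
    def volume(self) -> float:
        if self.volume_m3 is not None:
            return self.volume_m3
        return self.surface_area_km2 * 1e6 * self.mean_depth_m


@dataclass(frozen=True)
class Parcel:
    """A land-cover parcel within a sub-catchment."""

    category: str
    slope: SlopeClass
    area_ha: float

    def __post_init__(self):
        object.__setattr__(self, "category", resolve_category(self.category))
        object.__setattr__(self, "slope", SlopeClass.coerce(self.slope))
        if self.area_ha < 0:
            raise DomainError(f"parcel area must be >= 0, got {self.area_ha}")


#: Recognised extra point-source types.  ``wwtw_override`` replaces the
#: per-capita urban term instead of adding to it.
EXTRA_SOURCE_TYPES = ("fish_farm", "fish_cage", "birds", "deposition", "wwtw_override", "other")

_EXTRA_ALIASES = {
    "fish_cages": "fish_cage",
    "rain": "deposition",
    "atmospheric_deposition": "deposition",
    "geese": "birds",
}


def resolve_source_type(name: str) -> str:
    key = str(name).strip().lower()
    key = _EXTRA_ALIASES.get(key, key)
    if key not in EXTRA_SOURCE_TYPES:
        raise DomainError(
            f"unknown extra source type {name!r}; expected one of {EXTRA_SOURCE_TYPES}"
        )
    return key


@dataclass(frozen=True)
class ExtraSource:
    source_type: str
    load_kg_yr: float

    def __post_init__(self):
        object.__setattr__(self, "source_type", resolve_source_type(self.source_type))
        if self.load_kg_yr < 0:
            raise DomainError(f"extra-source load must be >= 0, got {self.load_kg_yr}")


@dataclass
class SubCatchment:
    """One sub-catchment: its land parcels, population-based sources,
    extra point sources, annual climate, and (optionally) its lake."""

    catchment_id: str
    downstream_id: Optional[str] = None
    land_area_ha: float = 0.0
    parcels: list[Parcel] = field(default_factory=list)
    urban_population: float = 0.0
    riparian_septic_population: float = 0.0
    extra_sources: list[ExtraSource] = field(default_factory=list)
    precip_mm: float = 0.0
    pet_mm: float = 0.0
    runoff_coeff: float = 1.0
    lake: Optional[WaterBody] = None

    def __post_init__(self):
        if self.land_area_ha < 0:
            raise DomainError(f"{self.catchment_id}: land area must be >= 0")
        if self.urban_population < 0 or self.riparian_septic_population < 0:
            raise DomainError(f"{self.catchment_id}: populations must be >= 0")
        if self.precip_mm < 0 or self.pet_mm < 0:
            raise DomainError(f"{self.catchment_id}: climate inputs must be >= 0")
        if self.runoff_coeff < 0:
            raise DomainError(f"{self.catchment_id}: runoff_coeff must be >= 0")
        parcel_area = sum(p.area_ha for p in self.parcels)
        if parcel_area > self.land_area_ha * (1 + 1e-9) + 1e-9:
            raise DomainError(
                f"{self.catchment_id}: parcel areas sum to {parcel_area:.3f} ha, "
                f"exceeding land area {self.land_area_ha:.3f} ha"
            )

    @property
    def parcel_area_ha(self) -> float:
        return sum(p.area_ha for p in self.parcels)


@dataclass
class SubCatchmentNetwork:
    """A forest of sub-catchments draining toward outlet nodes."""

    nodes: dict[str, SubCatchment]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for cid, sc in self.nodes.items():
            if sc.catchment_id != cid:
                raise NetworkError(f"node key {cid!r} != catchment_id {sc.catchment_id!r}")
            if sc.downstream_id is not None and sc.downstream_id not in self.nodes:
                raise NetworkError(
                    f"{cid}: downstream_id {sc.downstream_id!r} does not resolve"
                )
        # cycle check by walking downstream from every node
        for start in self.nodes:
            seen = {start}
            cur = self.nodes[start].downstream_id
            prev = start
            while cur is not None:
                if cur in seen:
                    raise NetworkError(f"cycle detected at edge {prev!r} -> {cur!r}")
                seen.add(cur)
                prev = cur
                cur = self.nodes[cur].downstream_id

    def upstream_ids(self, catchment_id: str) -> list[str]:
        return sorted(
            cid for cid, sc in self.nodes.items() if sc.downstream_id == catchment_id
        )

    def outlets(self) -> list[str]:
        return sorted(cid for cid, sc in self.nodes.items() if sc.downstream_id is None)

    def waterbodies(self) -> dict[str, WaterBody]:
        return {
            sc.lake.waterbody_id: sc.lake for sc in self.nodes.values() if sc.lake is not None
        }

    def copy(self) -> "SubCatchmentNetwork":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class WfdBreakpoints:
    """Per-waterbody TP class boundaries, ug P/l, strictly increasing:
    High/Good (hg), Good/Moderate (gm), Moderate/Poor (mp), Poor/Bad (pb)."""

    waterbody_id: str
    hg: float
    gm: float
    mp: float
    pb: float

    def __post_init__(self):
        bounds = (self.hg, self.gm, self.mp, self.pb)
        if not all(b > 0 for b in bounds) or not all(
            lo < hi for lo, hi in zip(bounds, bounds[1:])
        ):
            raise ConfigurationError(
                f"{self.waterbody_id}: breakpoints must be positive and strictly "
                f"increasing, got {bounds}"
            )

    @property
    def boundaries(self) -> tuple[float, float, float, float]:
        return (self.hg, self.gm, self.mp, self.pb)


@dataclass
class SourceApportionment:
    """Annual TP load (kg P/yr) broken down by source."""

    loads: dict[str, float]

    def __post_init__(self):
        for name, v in self.loads.items():
            if v < 0:
                raise DomainError(f"apportionment component {name!r} is negative: {v}")

    @property
    def total(self) -> float:
        return float(sum(self.loads.values()))

    def shares_percent(self) -> dict[str, float]:
        """Percentage share of each component; empty dict when total is 0."""
        t = self.total
        if t <= 0:
            return {}
        return {k: 100.0 * v / t for k, v in self.loads.items()}

    def merged(self, **extra: float) -> "SourceApportionment":
        loads = dict(self.loads)
        for k, v in extra.items():
            loads[k] = loads.get(k, 0.0) + v
        return SourceApportionment(loads)


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------

def _packaged_ec_path():
    return resources.files("phosload.data") / "export_coefficients.csv"


def load_defaults(
    config: "str | Mapping | None" = None,
) -> tuple[ExportCoefficientTable, PerCapitaRates, OecdParameters]:
    """Load the packaged default tables, optionally overridden by a config.

    ``config`` may be a mapping or a path to a YAML file with any of the
    keys ``export_coefficients`` (path to a CSV), ``per_capita``
    (``urban``/``septic``), ``oecd`` (``shallow_a``, ``shallow_b``,
    ``combined_a``, ``combined_b``, ``depth_threshold``).
    """
    if isinstance(config, (str,)) or hasattr(config, "read_text"):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    config = dict(config or {})

    ec_path = config.get("export_coefficients")
    try:
        if ec_path is not None:
            table = ExportCoefficientTable.from_csv(ec_path)
        else:
            with resources.as_file(_packaged_ec_path()) as p:
                table = ExportCoefficientTable.from_csv(p)
    except (OSError, pd.errors.ParserError) as exc:
        raise ConfigurationError(f"cannot read export-coefficient table: {exc}") from exc

    pc_cfg = dict(config.get("per_capita", {}))
    rates = PerCapitaRates(
        urban=float(pc_cfg.get("urban", 0.9125)),
        septic=float(pc_cfg.get("septic", 0.25)),
    )

    oc = dict(config.get("oecd", {}))
    params = OecdParameters(
        shallow=OecdPreset(float(oc.get("shallow_a", 1.02)), float(oc.get("shallow_b", 0.88))),
        combined=OecdPreset(float(oc.get("combined_a", 1.55)), float(oc.get("combined_b", 0.82))),
        depth_threshold=float(oc.get("depth_threshold", 3.0)),
    )
    return table, rates, params
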