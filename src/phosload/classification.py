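"""WFD status, trophic class, traffic light and headroom capacity.

Status is assigned by comparing a modelled TP concentration against the
waterbody's breakpoint ladder (High/Good, Good/Moderate, Moderate/Poor,
Poor/Bad).  Boundaries are inclusive upward: a concentration exactly on a
boundary keeps the better class.  Trophic state uses the conventional
10/20 ug P/l thresholds.  Headroom is the additional annual load a lake
can take before its predicted concentration crosses the upper boundary of
its current class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_types import DomainError, OecdParameters, WaterBody, WfdBreakpoints
from .lake_model import lake_concentration, load_for_concentration

__all__ = [
    "StatusClass",
    "TrophicClass",
    "TrafficLight",
    "Headroom",
    "ComparisonMatrix",
    "wfd_status",
    "trophic_class",
    "traffic_light",
    "headroom_load",
    "comparison_matrix",
]


class StatusClass(enum.Enum):
    """WFD ecological status for TP, High (pristine) to Bad."""

    HIGH = ("High", 0)
    GOOD = ("Good", 1)
    MODERATE = ("Moderate", 2)
    POOR = ("Poor", 3)
    BAD = ("Bad", 4)

    def __init__(self, label: str, rank: int):
        self.label = label
        self.rank = rank

    @classmethod
    def from_label(cls, label: str) -> "StatusClass":
        for member in cls:
            if member.label.lower() == str(label).strip().lower():
                return member
        raise DomainError(f"unknown status class: {label!r}")

    def __lt__(self, other: "StatusClass") -> bool:
        return self.rank < other.rank


class TrophicClass(enum.Enum):
    OLIGOTROPHIC = "oligotrophic"
    MESOTROPHIC = "mesotrophic"
    EUTROPHIC = "eutrophic"


class TrafficLight(enum.Enum):
    GREEN = "green"
    AMBER = "amber"
    RED = "red"


def wfd_status(conc_ug_l: float, bp: WfdBreakpoints) -> StatusClass:
    """Status class of a TP concentration against a breakpoint ladder."""
    if conc_ug_l < 0:
        raise DomainError(f"concentration must be >= 0, got {conc_ug_l}")
    if conc_ug_l <= bp.hg:
        return StatusClass.HIGH
    if conc_ug_l <= bp.gm:
        return StatusClass.GOOD
    if conc_ug_l <= bp.mp:
        return StatusClass.MODERATE
    if conc_ug_l <= bp.pb:
        return StatusClass.POOR
    return StatusClass.BAD


def trophic_class(conc_ug_l: float) -> TrophicClass:
    """Trophic state: <10 oligotrophic, 10-20 mesotrophic, >20 eutrophic."""
    if conc_ug_l < 0:
        raise DomainError(f"concentration must be >= 0, got {conc_ug_l}")
    if conc_ug_l < 10.0:
        return TrophicClass.OLIGOTROPHIC
    if conc_ug_l <= 20.0:
        return TrophicClass.MESOTROPHIC
    return TrophicClass.EUTROPHIC


def traffic_light(
    conc_ug_l: float,
    bp: WfdBreakpoints,
    target_boundary: str = "gm",
    amber_fraction: float = 0.10,
) -> TrafficLight:
    """Red/amber/green proximity of a concentration to a target boundary.

    Red above the boundary, amber within ``amber_fraction`` below it
    (boundary value included), green otherwise.
    """
    if not 0 < amber_fraction < 1:
        raise DomainError(f"amber_fraction must be in (0, 1), got {amber_fraction}")
    if conc_ug_l < 0:
        raise DomainError(f"concentration must be >= 0, got {conc_ug_l}")
    if target_boundary not in ("hg", "gm", "mp", "pb"):
        raise DomainError(f"unknown target boundary {target_boundary!r}")
    boundary = getattr(bp, target_boundary)
    if conc_ug_l > boundary:
        return TrafficLight.RED
    if conc_ug_l > (1.0 - amber_fraction) * boundary:
        return TrafficLight.AMBER
    return TrafficLight.GREEN


@dataclass(frozen=True)
class Headroom:
    """Remaining load capacity before the next class boundary."""

    load_kg_yr: float          # >= 0 by construction
    boundary: str              # which breakpoint it was measured against
    boundary_exceeded: bool    # True when the class cannot absorb any load


_CLASS_UPPER_BOUNDARY = {
    StatusClass.HIGH: "hg",
    StatusClass.GOOD: "gm",
    StatusClass.MODERATE: "mp",
    StatusClass.POOR: "pb",
}


def headroom_load(
    current_load_kg_yr: float,
    discharge_m3_yr: float,
    lake: WaterBody,
    bp: WfdBreakpoints,
    params: OecdParameters,
    force_preset: "str | None" = None,
) -> Headroom:
    """Additional annual load the lake can take before leaving its class.

    For a lake already at Bad status there is no further boundary; the
    headroom is 0 with the exceeded flag set.
    """
    pred = lake_concentration(
        current_load_kg_yr, discharge_m3_yr, lake, params, force_preset
    )
    status = wfd_status(pred.tp_lake, bp)
    if status is StatusClass.BAD:
        return Headroom(0.0, "pb", True)
    boundary = _CLASS_UPPER_BOUNDARY[status]
    boundary_load = load_for_concentration(
        getattr(bp, boundary), discharge_m3_yr, lake, params, force_preset
    )
    room = boundary_load - current_load_kg_yr
    if room < 0:
        # numerically on the wrong side of the boundary (conc == boundary)
        return Headroom(0.0, boundary, True)
    return Headroom(room, boundary, False)


@dataclass
class ComparisonMatrix:
    """Cross-tabulation of measured against modelled status classes."""

    counts: pd.DataFrame        # index = measured, columns = modelled
    n: int
    counts_by_offset: dict[int, int]   # |rank(modelled) - rank(measured)| -> n

    @property
    def exact_percent(self) -> float:
        return 100.0 * self.counts_by_offset.get(0, 0) / self.n if self.n else 0.0

    def within_percent(self, k: int) -> float:
        """Cumulative percentage of pairs within k classes of each other."""
        if self.n == 0:
            return 0.0
        hits = sum(v for off, v in self.counts_by_offset.items() if off <= k)
        return 100.0 * hits / self.n

    @property
    def within_one_percent(self) -> float:
        return self.within_percent(1)


def comparison_matrix(
    modelled: Sequence[StatusClass], measured: Sequence[StatusClass]
) -> ComparisonMatrix:
    """5x5 count matrix of (measured, modelled) class pairs with agreement
    percentages (exact and within-k classes)."""
    if len(modelled) != len(measured):
        raise DomainError(
            f"modelled ({len(modelled)}) and measured ({len(measured)}) lists differ"
        )
    labels = [c.label for c in StatusClass]
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    counts.index.name = "measured"
    counts.columns.name = "modelled"
    offsets: dict[int, int] = {}
    for mo, me in zip(modelled, measured):
        counts.loc[me.label, mo.label] += 1
        off = abs(mo.rank - me.rank)
        offsets[off] = offsets.get(off, 0) + 1
    return ComparisonMatrix(counts=counts, n=len(modelled), counts_by_offset=offsets)
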