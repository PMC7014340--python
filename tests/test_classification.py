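"""WFD status, trophic class, traffic light, headroom and the comparison matrix."""

import pytest
from hypothesis import given, strategies as st

from phosload.classification import (
    StatusClass,
    TrafficLight,
    TrophicClass,
    comparison_matrix,
    headroom_load,
    traffic_light,
    trophic_class,
    wfd_status,
)
from phosload.core_types import DomainError, WaterBody, WfdBreakpoints
from phosload.lake_model import lake_concentration
from phosload.synthetic import validation_class_pairs

BP = WfdBreakpoints("wb", 10.0, 20.0, 40.0, 80.0)


@pytest.mark.parametrize(
    "conc, expected",
    [
        (0.0, StatusClass.HIGH),
        (10.0, StatusClass.HIGH),     # boundary keeps the better class
        (20.0, StatusClass.GOOD),
        (20.001, StatusClass.MODERATE),
        (40.0, StatusClass.MODERATE),
        (80.0, StatusClass.POOR),
        (80.1, StatusClass.BAD),
    ],
)
def test_wfd_status_boundaries_inclusive_upward(conc, expected):
    assert wfd_status(conc, BP) is expected


def test_skene_breakpoints_assign_printed_classes():
    bp = WfdBreakpoints("skene", 13.0, 25.0, 50.0, 100.0)
    assert wfd_status(96.3, bp) is StatusClass.POOR
    assert wfd_status(135.4, bp) is StatusClass.BAD


@given(c1=st.floats(0, 500), c2=st.floats(0, 500))
def test_wfd_status_monotone_non_improving(c1, c2):
    lo, hi = sorted([c1, c2])
    assert wfd_status(lo, BP).rank <= wfd_status(hi, BP).rank


@pytest.mark.parametrize(
    "conc, expected",
    [
        (5.5, TrophicClass.OLIGOTROPHIC),
        (9.999, TrophicClass.OLIGOTROPHIC),
        (10.0, TrophicClass.MESOTROPHIC),
        (20.0, TrophicClass.MESOTROPHIC),
        (27.7, TrophicClass.EUTROPHIC),
    ],
)
def test_trophic_thresholds(conc, expected):
    assert trophic_class(conc) is expected


def test_traffic_light_bands():
    assert traffic_light(0.0, BP) is TrafficLight.GREEN
    assert traffic_light(17.9, BP) is TrafficLight.GREEN   # below 0.9 * gm
    assert traffic_light(18.5, BP) is TrafficLight.AMBER
    assert traffic_light(20.0, BP) is TrafficLight.AMBER   # on the boundary
    assert traffic_light(20.2, BP) is TrafficLight.RED
    with pytest.raises(DomainError):
        traffic_light(5.0, BP, amber_fraction=1.5)


def test_headroom_zero_at_boundary_and_decreasing(oecd):
    lake = WaterBody("wb", 1.0, 5.0)
    q = 1.0e7
    from phosload.lake_model import load_for_concentration

    boundary_load = load_for_concentration(BP.hg, q, lake, oecd)
    at_boundary = headroom_load(boundary_load, q, lake, BP, oecd)
    assert at_boundary.load_kg_yr == pytest.approx(0.0, abs=1e-6)

    h1 = headroom_load(boundary_load * 0.3, q, lake, BP, oecd)
    h2 = headroom_load(boundary_load * 0.6, q, lake, BP, oecd)
    assert h1.load_kg_yr > h2.load_kg_yr > 0
    assert not h1.boundary_exceeded


def test_consuming_headroom_flips_status(oecd):
    """Adding slightly more than the reported headroom crosses the class
    boundary; re-running the model confirms the downgrade."""
    lake = WaterBody("wb", 1.0, 5.0)
    q = 1.0e7
    load = 300.0
    hr = headroom_load(load, q, lake, BP, oecd)
    before = wfd_status(lake_concentration(load, q, lake, oecd).tp_lake, BP)
    after = wfd_status(
        lake_concentration(load + hr.load_kg_yr * 1.001, q, lake, oecd).tp_lake, BP
    )
    assert after.rank == before.rank + 1


def test_headroom_at_bad_status_is_flagged(oecd):
    lake = WaterBody("wb", 1.0, 2.0)
    hr = headroom_load(1e6, 1e6, lake, BP, oecd)
    assert hr.load_kg_yr == 0.0
    assert hr.boundary_exceeded


def test_comparison_matrix_identical_and_single_offset():
    same = [StatusClass.HIGH, StatusClass.POOR]
    cm = comparison_matrix(same, same)
    assert cm.exact_percent == 100.0
    assert (cm.counts.values.sum()) == 2
    one = comparison_matrix([StatusClass.GOOD], [StatusClass.HIGH])
    assert one.exact_percent == 0.0
    assert one.within_one_percent == 100.0
    with pytest.raises(DomainError):
        comparison_matrix([StatusClass.HIGH], [])


def test_comparison_matrix_reproduces_published_validation_summary():
    """The published 323-site cross-tabulation: 54.2% exact agreement and
    87.6% within one class."""
    modelled, measured = validation_class_pairs()
    cm = comparison_matrix(modelled, measured)
    assert cm.n == 323
    assert cm.counts_by_offset[0] == 175
    assert cm.counts_by_offset[1] == 108
    assert cm.counts_by_offset[2] == 35
    assert cm.counts_by_offset[3] == 5
    assert cm.exact_percent == pytest.approx(54.2, abs=0.05)
    assert cm.within_one_percent == pytest.approx(87.6, abs=0.05)
    assert cm.counts.loc["High", "High"] == 146
    assert cm.counts.loc["Good", "High"] == 53
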