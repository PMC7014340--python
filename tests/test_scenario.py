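"""Scenario application, purity, and the case-study what-if runs."""

import copy

import pytest

from phosload.core_types import DomainError
from phosload.io import run_pipeline
from phosload.scenario import (
    AddExtraSource,
    ClimateScaling,
    LandCoverTransfer,
    PopulationChange,
    Scenario,
    apply_scenario,
    diff_report,
    load_scenario,
)
from phosload.synthetic import generate_breakpoints, generate_network


@pytest.fixture(scope="module")
def small_net():
    return generate_network(6, seed=7, profile="lowland")


@pytest.fixture(scope="module")
def small_bps(small_net):
    return generate_breakpoints(small_net)


def test_empty_change_set_is_identity(small_net, small_bps):
    out = apply_scenario(small_net, [])
    assert run_pipeline(out, small_bps).equals(run_pipeline(small_net, small_bps))


def test_scenario_application_is_pure(small_net, small_bps):
    baseline = run_pipeline(small_net, small_bps)
    snapshot = copy.deepcopy(small_net)
    cid = next(iter(small_net.nodes))
    apply_scenario(
        small_net,
        [AddExtraSource(cid, "fish_farm", 500.0), ClimateScaling(precip_factor=1.2),
         PopulationChange(cid, urban_population=9999.0)],
    )
    again = run_pipeline(small_net, small_bps)
    assert again.equals(baseline)
    assert small_net.nodes[cid].extra_sources == snapshot.nodes[cid].extra_sources


def test_land_cover_transfer_conserves_area_and_caps_at_available(small_net):
    cid, sc = next(
        (c, s) for c, s in small_net.nodes.items()
        if any(p.category == "Arable" and p.area_ha > 0 for p in s.parcels)
    )
    arable = sum(p.area_ha for p in sc.parcels if p.category == "Arable")
    before = sc.parcel_area_ha
    out = apply_scenario(
        small_net, [LandCoverTransfer(cid, "Arable", "Improved grassland", arable / 2)]
    )
    assert out.nodes[cid].parcel_area_ha == pytest.approx(before, rel=1e-12)
    with pytest.raises(DomainError, match="transfer"):
        apply_scenario(
            small_net, [LandCoverTransfer(cid, "Arable", "Wetland", arable * 2)]
        )


def test_unknown_catchment_rejected(small_net):
    with pytest.raises(DomainError, match="unknown catchment"):
        apply_scenario(small_net, [AddExtraSource("nope", "birds", 1.0)])


def test_diff_report_zero_for_identical_runs(small_net, small_bps):
    df = run_pipeline(small_net, small_bps)
    rep = diff_report(df, df)
    assert (rep["load_delta_kg_yr"] == 0).all()
    assert (rep["conc_delta_ug_l"] == 0).all()
    assert (rep["class_transition"] == "").all()


def test_milton_all_arable_scenario(case_fixtures):
    fx = case_fixtures["milton"]
    base = run_pipeline(fx.network, fx.breakpoints)
    assert base.loc[0, "tp_lake_ug_l"] == pytest.approx(20.1, abs=0.05)
    scen = apply_scenario(fx.network, fx.scenario)
    out = run_pipeline(scen, fx.breakpoints)
    assert out.loc[0, "tp_lake_ug_l"] == pytest.approx(37.4, abs=0.05)
    # every parcel is now arable
    assert {p.category for p in scen.nodes["milton"].parcels} == {"Arable"}


def test_skene_correction_scenario(case_fixtures):
    fx = case_fixtures["skene"]
    base = run_pipeline(fx.network, fx.breakpoints)
    assert base.loc[0, "tp_lake_ug_l"] == pytest.approx(135.4, abs=0.05)
    assert base.loc[0, "wfd_class"] == "Bad"
    out = run_pipeline(apply_scenario(fx.network, fx.scenario), fx.breakpoints)
    assert out.loc[0, "tp_lake_ug_l"] == pytest.approx(60.4, abs=0.05)
    assert out.loc[0, "wfd_class"] == "Poor"


def test_leven_preset_scenario_delta(case_fixtures):
    fx = case_fixtures["leven"]
    base = run_pipeline(fx.network, fx.breakpoints)
    scen = run_pipeline(
        apply_scenario(fx.network, fx.scenario), fx.breakpoints,
        force_preset=fx.scenario.force_preset,
    )
    rep = diff_report(base, scen)
    assert rep.loc[0, "conc_delta_ug_l"] == pytest.approx(45.9 - 53.8, abs=0.1)


def test_menteith_extras_record_class_transition(case_fixtures):
    fx = case_fixtures["menteith"]
    base = run_pipeline(fx.network, fx.breakpoints)
    scen = run_pipeline(apply_scenario(fx.network, fx.scenario), fx.breakpoints)
    rep = diff_report(base, scen)
    assert rep.loc[0, "class_transition"] == "High->Good"
    assert rep.loc[0, "load_delta_kg_yr"] == pytest.approx(227.0, abs=1e-9)


def test_scenario_yaml_round_trip(tmp_path):
    doc = """
name: demo
force_preset: shallow
changes:
  - type: land_cover_transfer
    catchment_id: c1
    from_category: Arable
    to_category: Wetland
    area_ha: 10
  - type: add_extra_source
    catchment_id: c1
    source_type: birds
    load_kg_yr: 42
"""
    path = tmp_path / "scen.yaml"
    path.write_text(doc)
    scen = load_scenario(path)
    assert scen.name == "demo"
    assert scen.force_preset == "shallow"
    assert isinstance(scen.changes[0], LandCoverTransfer)
    assert scen.changes[1].load_kg_yr == 42
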