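"""Default constants, the export-coefficient registry, and type invariants."""

import math

import pytest

from phosload.core_types import (
    CategoryLookupError,
    ConfigurationError,
    DomainError,
    ECRange,
    LAND_COVER_CATEGORIES,
    PerCapitaRates,
    SlopeClass,
    SubCatchment,
    SubCatchmentNetwork,
    WaterBody,
    WfdBreakpoints,
    load_defaults,
    resolve_category,
)

# The full published median coefficient table, kg P/ha/yr, (Low, Medium, High).
TABLE_MEDIANS = {
    "Water": (0.135, 0.135, 0.135),
    "Wetland": (0.085, 0.085, 0.085),
    "Blanket bog & peatland": (0.020, 0.030, 0.040),
    "Arable": (0.740, 1.140, 1.540),
    "Improved grassland": (0.320, 0.470, 0.620),
    "Coarse grassland, Smooth grassland, Heather all types, Bracken": (0.060, 0.090, 0.115),
    "Cliffs": (0.045, 0.045, 0.045),
    "Montane vegetation": (0.025, 0.040, 0.060),
    "Low scrub": (0.140, 0.190, 0.240),
    "Broadleaved woodland": (0.150, 0.215, 0.275),
    "Mixed woodland, Open canopy young plantation": (0.125, 0.175, 0.235),
    "Coniferous plantation": (0.100, 0.145, 0.195),
    "Recently ploughed land": (0.560, 0.760, 0.960),
    "Woodland recently felled": (0.360, 0.560, 0.760),
    "Ripping": (0.300, 0.365, 0.425),
    "Estuary, Salt marsh, Dune land, Maritime grasslands & heaths": (0.0, 0.0, 0.0),
    "Airfields, Recreational land, Quarries, Other land, Road & rail": (0.0, 0.0, 0.0),
    "Factories & urban": (1.380, 2.105, 2.830),
}


def test_default_constants(rates, oecd):
    assert rates.urban == 0.9125
    assert rates.septic == 0.25
    assert oecd.depth_threshold == 3.0
    assert (oecd.shallow.a, oecd.shallow.b) == (1.02, 0.88)
    assert (oecd.combined.a, oecd.combined.b) == (1.55, 0.82)


def test_packaged_medians_match_published_table(ec_table):
    for cat, meds in TABLE_MEDIANS.items():
        for slope, med in zip(SlopeClass, meds):
            assert ec_table.coefficient(cat, slope, "median") == med


def test_slope_invariant_categories_resolve_identically(ec_table):
    for cat, value in (("Water", 0.135), ("Wetland", 0.085), ("Cliffs", 0.045)):
        assert {ec_table.coefficient(cat, s) for s in SlopeClass} == {value}


def test_table_invariants_and_range_anchors(ec_table):
    for rng in ec_table.entries.values():
        assert 0 <= rng.min <= rng.median <= rng.max
    wet = ec_table.range_for("Wetland", SlopeClass.LOW)
    assert wet.max / wet.min == pytest.approx(7.5)
    grass = ec_table.range_for("Coarse grassland", SlopeClass.HIGH)
    assert grass.max / grass.min == pytest.approx(1.875)


def test_category_registry_rejects_unknown_names(ec_table):
    assert resolve_category("heather") == (
        "Coarse grassland, Smooth grassland, Heather all types, Bracken"
    )
    with pytest.raises(CategoryLookupError, match="maize"):
        resolve_category("maize")
    with pytest.raises(CategoryLookupError):
        ec_table.coefficient("maize", SlopeClass.LOW)


def test_every_registry_category_resolves_for_every_slope(ec_table):
    for cat in LAND_COVER_CATEGORIES:
        for slope in SlopeClass:
            for setting in ("min", "median", "max"):
                assert ec_table.coefficient(cat, slope, setting) >= 0


def test_defaults_round_trip_bit_exact(ec_table, tmp_path):
    path = tmp_path / "ec.csv"
    ec_table.to_csv(path)
    again = type(ec_table).from_csv(path)
    assert again.entries == ec_table.entries


def test_config_overrides(tmp_path):
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text("per_capita:\n  urban: 0.6\noecd:\n  depth_threshold: 5.0\n")
    _, rates, params = load_defaults(str(cfg))
    assert rates.urban == 0.6
    assert rates.septic == 0.25
    assert params.depth_threshold == 5.0


def test_invalid_inputs_rejected():
    with pytest.raises(ConfigurationError):
        ECRange(0.5, 0.4, 0.6)  # min > median
    with pytest.raises(DomainError):
        PerCapitaRates(urban=-1.0)
    with pytest.raises(DomainError):
        WaterBody("w", surface_area_km2=0.0, mean_depth_m=2.0)
    with pytest.raises(ConfigurationError):
        WfdBreakpoints("w", 10, 10, 20, 30)  # not strictly increasing
    with pytest.raises(DomainError):
        SubCatchment("c", land_area_ha=-5)


def test_waterbody_volume_defaults_to_area_times_depth():
    wb = WaterBody("w", surface_area_km2=2.0, mean_depth_m=3.0)
    assert wb.volume == pytest.approx(6.0e6)
    assert WaterBody("w", 2.0, 3.0, volume_m3=5e6).volume == 5e6


def test_network_rejects_cycles_and_dangling_links():
    a = SubCatchment("a", downstream_id="b", land_area_ha=1)
    b = SubCatchment("b", downstream_id="a", land_area_ha=1)
    with pytest.raises(Exception, match="cycle"):
        SubCatchmentNetwork({"a": a, "b": b})
    c = SubCatchment("c", downstream_id="missing", land_area_ha=1)
    with pytest.raises(Exception, match="resolve"):
        SubCatchmentNetwork({"c": c})
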