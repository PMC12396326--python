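import dataclasses

import numpy as np
import pandas as pd
import pytest

from paleocarb.grid import make_domain
from paleocarb.world import (
    BIOME_CLASSES,
    BiomeRules,
    ConfigurationError,
    InvalidScenarioError,
    LoessRegionSpec,
    NO_BIOME,
    REFERENCE_MODEL,
    BIASED_MODEL,
    Scenario,
    apply_peat_initiation_rule,
    build_world,
    make_loess_regions,
    make_peat_curves,
    sample_pollen_sites,
    simulate_climate,
    simulate_ice_and_sea,
)


# --- climate ----------------------------------------------------------------


def test_climate_deterministic_given_seed():
    d = make_domain(1.0)
    sc = Scenario()
    a = simulate_climate(d, sc, seed=11)
    b = simulate_climate(d, sc, seed=11)
    c = simulate_climate(d, sc, seed=12)
    assert a[REFERENCE_MODEL].maat.equals(b[REFERENCE_MODEL].maat)
    assert not a[REFERENCE_MODEL].maat.equals(c[REFERENCE_MODEL].maat)


def test_climate_requires_seed():
    with pytest.raises(InvalidScenarioError):
        simulate_climate(make_domain(1.0), Scenario(), seed=None)


def test_climate_slice_invariants(world):
    for ds in world.climates.values():
        assert (ds.t_cold <= ds.maat).all() and (ds.maat <= ds.t_warm).all()
        assert np.allclose(ds.t_range, ds.t_warm - ds.t_cold)
        assert (ds.pr_gs <= ds.pr_ann).all() and (ds.pr_ann >= 0).all()


def test_lgm_colder_than_preindustrial(world):
    ref = world.climates[REFERENCE_MODEL].maat
    assert float(ref.sel(time=21).mean()) < float(ref.sel(time=0).mean())


def test_intermodel_bias_is_constant_everywhere(world):
    diff = world.climates[BIASED_MODEL].maat - world.climates[REFERENCE_MODEL].maat
    bias = world.scenario.model_bias_c[BIASED_MODEL]
    assert np.allclose(diff.values, bias)


# --- ice, sea, masks --------------------------------------------------------


def test_ice_retreat_monotone_and_residual(world):
    area = (world.truth.ice.values * world.domain.cell_area).sum(axis=(1, 2))
    assert np.all(np.diff(area) <= 0)  # time runs 21 -> 0
    # from 4 ka on only the residual (Greenland-analogue) ice remains
    residual = (world.truth.ice.sel(time=0).values * world.domain.cell_area).sum()
    at_4ka = (world.truth.ice.sel(time=4).values * world.domain.cell_area).sum()
    assert at_4ka == pytest.approx(residual)


def test_cold_based_subset_of_ice(world):
    assert not np.any(world.truth.cold_based.values & ~world.truth.ice.values)


def test_mask_algebra_partition(world):
    ice = world.truth.ice.values
    land = world.truth.land.values
    assert not np.any(ice & land)  # ice and land disjoint; rest is ocean


def test_sea_level_only_rises_outside_glaciated_cells(world):
    ever_iced = world.truth.ice.values.any(axis=0)
    land21 = world.land(21) | world.truth.ice.sel(time=21).values
    gained = world.land(0) & ~land21 & ~ever_iced
    assert not gained.any()


def test_lgm_shelf_is_ocean_again_by_present(world):
    assert world.shelf(21).any()
    assert not world.shelf(0).any()


def test_land_area_bookkeeping_identity(world):
    a = world.domain.cell_area
    land_delta = float((world.land(21) * a).sum() - (world.land(0) * a).sum())
    shelf_loss = float((world.shelf(21) * a).sum())
    degl_gain = float(((world.land(0) & ~world.land(21)) * a).sum())
    assert land_delta == pytest.approx(shelf_loss - degl_gain, rel=1e-9)


def test_non_monotone_retreat_rejected():
    sc = Scenario(ice_line_anchors={21: 48.0, 10: 60.0, 8: 55.0, 5: 91.0})
    with pytest.raises(InvalidScenarioError):
        simulate_ice_and_sea(make_domain(1.0), sc, seed=1)


# --- true biomes ------------------------------------------------------------


def test_biome_rules_thresholds():
    rules = BiomeRules()
    code = rules.classify(np.array([-10.0]), np.array([7.0]), np.array([500.0]))
    assert BIOME_CLASSES[code[0]] == "tundra"
    code = rules.classify(np.array([15.0]), np.array([25.0]), np.array([50.0]))
    assert BIOME_CLASSES[code[0]] == "desert"


def test_ice_cells_have_no_biome(world):
    b = world.truth.biome_true.values
    ice = world.truth.ice.values
    land = world.truth.land.values
    assert np.all(b[ice] == NO_BIOME)
    assert np.all(b[land] >= 0)  # every unglaciated land cell labeled


def test_biome_rules_deterministic(world):
    rules = world.scenario.biome_rules
    clim = world.climates[REFERENCE_MODEL].sel(time=6)
    a = rules.classify(clim.maat.values, clim.t_warm.values, clim.pr_ann.values)
    b = rules.classify(clim.maat.values, clim.t_warm.values, clim.pr_ann.values)
    assert np.array_equal(a, b)


def test_incoherent_rules_rejected():
    with pytest.raises(ConfigurationError):
        BiomeRules(boreal_maat_c=12.0, temperate_maat_c=11.0).validate()


# --- training samples -------------------------------------------------------


def _truth_at_sites(world, df):
    iy = (df["lat"].to_numpy() - 23.5).round().astype(int)
    ix = (df["lon"].to_numpy() + 179.5).round().astype(int)
    t = df["time_ka"].to_numpy()
    bt = world.truth.biome_true
    return np.array(
        [int(bt.sel(time=tt).values[y, x]) for tt, y, x in zip(t, iy, ix)]
    )


def test_zero_noise_labels_equal_truth(world):
    df = sample_pollen_sites(world, 50, 0.0, 0.1, seed=5, times=(0, 6, 21))
    codes = df["biome"].map({c: i for i, c in enumerate(BIOME_CLASSES)}).to_numpy()
    assert np.array_equal(codes, _truth_at_sites(world, df))


def test_training_row_count(world):
    df = sample_pollen_sites(world, 100, 0.0, 0.0, seed=5, times=tuple(range(10)))
    assert len(df) == 1000
    assert set(df["time_ka"]) == set(range(10))


def test_label_noise_rate_binomial(world):
    noise, n = 0.2, 500
    df = sample_pollen_sites(world, n, noise, 0.0, seed=5)
    mism = (df["biome"].map({c: i for i, c in enumerate(BIOME_CLASSES)}).to_numpy()
            != _truth_at_sites(world, df))
    total = len(df)
    rate = mism.mean()
    assert abs(rate - noise) < 3 * np.sqrt(noise * (1 - noise) / total)


# --- loess ------------------------------------------------------------------


def test_loess_calibrated_total(world):
    assert world.loess_table["stock_frozen_pgc"].sum() == pytest.approx(363.0)


def test_loess_thawed_density_must_be_lower():
    d = make_domain(1.0)
    spec = LoessRegionSpec("bad", 0, 10, 40, 45, 10.0, 5.0, 6.0)
    with pytest.raises(InvalidScenarioError):
        make_loess_regions(d, [spec], np.ones(d.shape, dtype=bool))


def test_zero_regions_zero_stock():
    d = make_domain(1.0)
    _, table = make_loess_regions(d, [], np.ones(d.shape, dtype=bool))
    assert table["stock_frozen_pgc"].sum() == 0.0


def test_loess_stock_linear_in_area():
    d = make_domain(1.0)
    base = np.ones(d.shape, dtype=bool)
    one = [LoessRegionSpec("a", 0, 10, 40, 45, 10.0, 16.0, 1.6)]
    two = one + [LoessRegionSpec("b", 20, 30, 40, 45, 10.0, 16.0, 1.6)]
    _, t1 = make_loess_regions(d, one, base)
    _, t2 = make_loess_regions(d, two, base)
    assert t2["stock_frozen_pgc"].sum() == pytest.approx(2 * t1["stock_frozen_pgc"].sum())


# --- peat -------------------------------------------------------------------


def test_peat_curves_boundary_conditions():
    curves = make_peat_curves(Scenario())
    assert curves.stock_at(0) == pytest.approx(1.0)
    assert curves.area_at(0) == pytest.approx(1.0)
    assert curves.stock_at(16) == pytest.approx(0.0, abs=1e-12)
    # monotone as t -> 0 (arrays run 21 -> 0 ka)
    assert np.all(np.diff(curves.stock_fraction) >= 0)
    assert np.all(np.diff(curves.area_fraction) >= 0)
    assert curves.pi_total_stock_pgc == 450.0


def test_peat_curves_reject_bad_shape():
    with pytest.raises(InvalidScenarioError):
        make_peat_curves(dataclasses.replace(Scenario(), peat_stock_scale_ka=-1.0))


def test_southern_cells_default_initiation():
    lat2 = np.array([[35.0, 45.0]])
    init = np.array([[np.nan, np.nan]])
    out = apply_peat_initiation_rule(init, lat2)
    assert out[0, 0] == 12.0  # 35N without data -> assumed 12 ka
    assert np.isnan(out[0, 1])  # rule only fills south of 38N


# --- whole world ------------------------------------------------------------


def test_world_deterministic_given_seed():
    a = build_world(seed=13)
    b = build_world(seed=13)
    assert a.climates[REFERENCE_MODEL].maat.equals(b.climates[REFERENCE_MODEL].maat)
    assert np.array_equal(a.truth.biome_true.values, b.truth.biome_true.values)
    assert np.array_equal(a.truth.peat_pi_frac.values, b.truth.peat_pi_frac.values)
    pd.testing.assert_frame_equal(a.loess_table, b.loess_table)


def test_world_roundtrip_to_disk(tmp_path, world):
    world.save(tmp_path)
    assert (tmp_path / "world.nc").exists()
    curves = pd.read_csv(tmp_path / "peat_curves.csv")
    assert curves["stock_fraction"].iloc[-1] == pytest.approx(1.0)
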