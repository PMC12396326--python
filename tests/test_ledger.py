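import numpy as np
import pytest

from paleocarb.ledger import (
    ACCRUAL_K_PER_KA,
    CarbonState,
    LedgerError,
    TransferFunctionTable,
    average_models,
    gross_changes,
    loess_anchor_trajectory,
    loess_step,
    mineral_stock,
    net_change,
    peat_step,
    peat_uncertainty_frac,
    postglacial_accrual,
    shelf_transfer,
    subglacial_step,
    subglacial_stock,
)
from paleocarb.world import BIOME_CLASSES, Scenario, make_peat_curves


def _single_cell_inputs(tundra=0.6, boreal=0.4, peat=0.0, slope=0.0):
    frac = np.zeros((8, 1, 1))
    frac[BIOME_CLASSES.index("tundra"), 0, 0] = tundra
    frac[BIOME_CLASSES.index("boreal forest"), 0, 0] = boreal
    tf = TransferFunctionTable()
    for c in BIOME_CLASSES:
        tf.densities[(c, "no-permafrost")] = (0.0, 0.0)
    tf.densities[("tundra", "no-permafrost")] = (30.0, 0.0)
    tf.densities[("boreal forest", "no-permafrost")] = (15.0, 0.0)
    kw = dict(
        fractions=frac,
        tf=tf,
        pf_continuous=np.zeros((1, 1), dtype=bool),
        peat_frac=np.full((1, 1), peat),
        slope_frac=np.full((1, 1), slope),
        cell_area=np.full((1, 1), 1e10),
        land_mask=np.ones((1, 1), dtype=bool),
        shelf_mask=np.zeros((1, 1), dtype=bool),
    )
    return kw


class TestMineralStock:
    def test_two_biome_cell_arithmetic(self):
        # 0.6*30 + 0.4*15 = 24 kg/m2 over 1e10 m2 -> 0.24 Pg
        out = mineral_stock(**_single_cell_inputs())
        assert out["mineral_land"][0] == pytest.approx(0.24)

    def test_slope_rule(self):
        out = mineral_stock(**_single_cell_inputs(slope=0.1))
        expected = (0.9 * 24.0 + 0.1 * 3.0) * 1e10 * 1e-12
        assert out["mineral_land"][0] == pytest.approx(expected)

    def test_full_peat_cover_excludes_mineral(self):
        out = mineral_stock(**_single_cell_inputs(peat=1.0))
        assert out["mineral_land"][0] == pytest.approx(0.0)

    def test_fractions_exceeding_one_rejected(self):
        with pytest.raises(LedgerError, match="cell"):
            mineral_stock(**_single_cell_inputs(peat=0.7, slope=0.5))

    def test_permafrost_state_switches_density(self):
        kw = _single_cell_inputs(tundra=1.0, boreal=0.0)
        kw["tf"].densities[("tundra", "permafrost")] = (40.0, 0.0)
        kw["pf_continuous"] = np.ones((1, 1), dtype=bool)
        out = mineral_stock(**kw)
        assert out["mineral_land"][0] == pytest.approx(0.40)

    def test_missing_transfer_function_rejected(self):
        kw = _single_cell_inputs()
        del kw["tf"].densities[("desert", "no-permafrost")]
        with pytest.raises(LedgerError, match="desert"):
            mineral_stock(**kw)


class TestAverageModels:
    def test_identical_inputs_unchanged(self):
        a = mineral_stock(**_single_cell_inputs())
        out = average_models(a, a)
        assert out["mineral_land"] == a["mineral_land"]

    def test_mean_splits_the_difference(self):
        a = mineral_stock(**_single_cell_inputs())
        b = mineral_stock(**_single_cell_inputs(tundra=1.0, boreal=0.0))
        out = average_models(a, b)
        expected = 0.5 * (a["mineral_land"][0] + b["mineral_land"][0])
        assert out["mineral_land"][0] == pytest.approx(expected)
        assert "intermodel_gap_pct_of_sd" in out

    def test_mismatched_grids_rejected(self):
        a = mineral_stock(**_single_cell_inputs())
        b = dict(a)
        b["map"] = np.zeros((2, 2))
        with pytest.raises(LedgerError):
            average_models(a, b)


class TestLoess:
    def test_fully_frozen_region_unchanged(self):
        state = {"r": {"frozen": 100.0, "thawed": 0.0}}
        new, losses = loess_step(state, {"r": 1.0}, {"r": 1.0})
        assert new["r"]["frozen"] == 100.0
        assert losses["r"] == 0.0

    def test_half_thaw_arithmetic(self):
        # 100 Pg, thawed fraction 0.5, retention 0.1 -> loss 45 Pg
        state = {"r": {"frozen": 100.0, "thawed": 0.0}}
        new, losses = loess_step(state, {"r": 1.0}, {"r": 0.5}, retention_on_thaw=0.1)
        assert losses["r"] == pytest.approx(45.0)
        assert new["r"]["frozen"] == pytest.approx(50.0)
        assert new["r"]["thawed"] == pytest.approx(5.0)

    def test_deposition_era_adds_stock(self):
        state = {"r": {"frozen": 100.0, "thawed": 0.0}}
        new, _ = loess_step(state, {"r": 1.0}, {"r": 1.0}, deposition_pgc={"r": 8.75})
        assert new["r"]["frozen"] == pytest.approx(108.75)

    def test_negative_stock_rejected(self):
        with pytest.raises(LedgerError):
            loess_step({"r": {"frozen": -1.0, "thawed": 0.0}}, {"r": 1.0}, {"r": 1.0})

    def test_anchor_trajectory_interpolates(self):
        anchors = {21: 363.0, 17: 398.0, 0: 57.0}
        traj = loess_anchor_trajectory(anchors, [21, 19, 17, 0])
        assert traj[0] == 363.0 and traj[2] == 398.0 and traj[3] == 57.0
        assert traj[1] == pytest.approx(380.5)


class TestPeat:
    def _world_bits(self, world):
        return dict(
            land_mask=world.land(0),
            peat_init=world.truth.peat_init.values,
            peat_pi_frac=world.truth.peat_pi_frac.values,
            cell_area=world.domain.cell_area,
        )

    def test_pi_pool_total_450(self, world):
        curves = make_peat_curves(Scenario())
        out = peat_step(curves, 0, **self._world_bits(world))
        assert out["peat"][0] == pytest.approx(450.0)
        assert out["map"].sum() == pytest.approx(450.0, abs=1e-6)

    def test_glacial_pool_zero_with_50pct_ramp(self, world):
        curves = make_peat_curves(Scenario())
        out = peat_step(curves, 16, **self._world_bits(world))
        assert out["peat"][0] == pytest.approx(0.0, abs=1e-9)
        assert peat_uncertainty_frac(16) == pytest.approx(
            np.sqrt(0.10**2 + 0.36**2 + 0.50**2)
        )

    def test_pool_monotone_toward_present(self, world):
        curves = make_peat_curves(Scenario())
        bits = self._world_bits(world)
        totals = [peat_step(curves, t, **bits)["peat"][0] for t in range(16, -1, -1)]
        assert np.all(np.diff(totals) >= 0)

    def test_no_eligible_cells_is_an_error(self, world):
        curves = make_peat_curves(Scenario())
        bits = self._world_bits(world)
        bits["peat_init"] = np.zeros_like(bits["peat_init"])  # nothing initiated
        with pytest.raises(LedgerError):
            peat_step(curves, 8, **bits)

    def test_cell_fraction_capped_at_pi_extent(self, world):
        curves = make_peat_curves(Scenario())
        bits = self._world_bits(world)
        out = peat_step(curves, 4, **bits)
        assert np.all(out["frac"] <= bits["peat_pi_frac"] + 1e-9)


class TestAccrual:
    def test_zero_time_zero_stock(self):
        assert postglacial_accrual(0.0, "boreal forest", 10.0, 5.0) == 0.0

    def test_asymptote_is_equilibrium(self):
        assert postglacial_accrual(1e6, "tundra", 10.0, 5.0) == pytest.approx(15.0)

    def test_boreal_reaches_95pct_in_three_millennia(self):
        ce = 15.0
        k = ACCRUAL_K_PER_KA["boreal forest"]
        expected = ce * (1 - np.exp(-3 * k))  # direct evaluation of design rule
        got = postglacial_accrual(3.0, "boreal forest", 10.0, 5.0)
        assert got == pytest.approx(expected)
        assert got >= 0.95 * ce

    def test_grassland_falls_short_at_three_millennia(self):
        assert postglacial_accrual(3.0, "grassland/dry shrubland", 10.0, 5.0) < 0.95 * 15.0

    def test_unknown_class_rejected(self):
        with pytest.raises(LedgerError):
            postglacial_accrual(1.0, "kelp forest", 1.0, 1.0)


class TestSubglacial:
    def test_no_retreat_no_release(self):
        _, release = subglacial_step(1e12, 1e12)
        assert release == 0.0

    def test_full_disappearance_arithmetic(self):
        area, d, p = 1e12, 40.0, 50.0
        _, release = subglacial_step(area, 0.0)
        assert release == pytest.approx((area * d + 0.01 * area * p) * 1e-12)

    def test_readvance_rejected_by_default(self):
        with pytest.raises(LedgerError):
            subglacial_step(1e11, 2e11)
        _, release = subglacial_step(1e11, 2e11, allow_readvance=True)
        assert release < 0

    def test_stock_linear_in_area(self):
        a1, _ = subglacial_stock(1e12)
        a2, _ = subglacial_stock(2e12)
        assert a2 == pytest.approx(2 * a1)


class TestShelfTransfer:
    def _masks(self):
        land_pi = np.array([[True, False, False]])
        land_old = np.array([[True, True, True]])  # two shelf cells exposed
        land_new = np.array([[True, True, False]])  # outer cell drowns
        return land_old, land_new, land_pi

    def test_no_shoreline_change_no_flux(self):
        land_old, _, land_pi = self._masks()
        out = shelf_transfer(land_old, land_old, land_pi, np.full((1, 3), 5.0))
        assert out["transferred_pgc"] == 0.0
        assert out["cycled_flux_pgc"] == 0.0

    def test_cycled_flux_is_30pct_of_transfer(self):
        land_old, land_new, land_pi = self._masks()
        stock = np.array([[10.0, 20.0, 40.0]])
        out = shelf_transfer(land_old, land_new, land_pi, stock, cycling_fraction=0.30)
        assert out["transferred_pgc"] == pytest.approx(40.0)
        assert out["cycled_flux_pgc"] == pytest.approx(12.0)

    def test_total_stock_conserved(self):
        land_old, land_new, land_pi = self._masks()
        stock = np.array([[10.0, 20.0, 40.0]])
        exposed_before = stock[land_old & ~land_pi].sum()
        out = shelf_transfer(land_old, land_new, land_pi, stock, inundated_pool_old=7.0)
        exposed_after = stock[land_new & ~land_pi].sum()
        assert exposed_before + 7.0 == pytest.approx(
            exposed_after + out["inundated_pool_pgc"]
        )

    def test_shelf_reemergence_rejected(self):
        land_old, land_new, land_pi = self._masks()
        with pytest.raises(LedgerError):
            shelf_transfer(land_new, land_old, land_pi, np.zeros((1, 3)))

    def test_cycling_fraction_range_enforced(self):
        land_old, land_new, land_pi = self._masks()
        with pytest.raises(LedgerError):
            shelf_transfer(land_old, land_new, land_pi, np.zeros((1, 3)),
                           cycling_fraction=0.9)


def _state(time, **pools):
    full = {p: pools.get(p, (0.0, 0.0)) for p in
            ("mineral_land", "peat", "loess_deep")}
    return CarbonState(time=time, pools=full)


class TestNetChange:
    def test_identical_states_zero_record(self):
        a = _state(12, mineral_land=(100.0, 10.0))
        b = _state(11, mineral_land=(100.0, 10.0))
        fr = net_change(a, b)
        assert fr.total_stock_delta == 0.0
        assert fr.net_to_atmosphere_pgc == 0.0
        assert fr.net_uncertainty_pgc == 0.0

    def test_decomposition_sums_exactly(self):
        a = _state(12, mineral_land=(100.0, 5.0), peat=(20.0, 2.0))
        b = _state(11, mineral_land=(110.0, 5.0), peat=(16.0, 2.0))
        fr = net_change(a, b, cycled_flux_pgc=3.0)
        assert fr.pool_deltas["mineral_land"] == 10.0
        assert fr.pool_deltas["peat"] == -4.0
        assert fr.total_stock_delta == pytest.approx(6.0)
        assert fr.net_to_atmosphere_pgc == pytest.approx(6.0 - 3.0)

    def test_non_consecutive_times_rejected(self):
        with pytest.raises(LedgerError):
            net_change(_state(12), _state(10))


class TestGrossChanges:
    def test_identical_maps(self):
        m = np.ones((3, 3))
        assert gross_changes(m, m) == (0.0, 0.0)

    def test_signed_split(self):
        old = np.array([[0.0, 3.0]])
        new = np.array([[5.0, 0.0]])
        gains, losses = gross_changes(old, new)
        assert (gains, losses) == (5.0, -3.0)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(3)
        old, new = rng.random((2, 10, 10))
        gains, losses = gross_changes(old, new)
        net = new.sum() - old.sum()
        assert gains + losses == pytest.approx(net)
        assert abs(gains) + abs(losses) >= abs(net) - 1e-12
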