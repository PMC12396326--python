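"""Carbon-pool bookkeeping.

Every pool of the reconstruction is carried per millennium with a mean and
an SD: mineral soil on land (0-2 m), mineral soil on the exposed and the
inundated shelf, peat, deep loess (below 2 m), carbon beneath cold-based
ice, and post-glacial accruing soils.  Millennium-to-millennium net changes
decompose exactly into per-pool deltas plus the inundation cycling flux,
which is counted toward net changes but never toward stocks.

Unit conventions: areas m^2, densities kg C m^-2 (0-2 m column) or
kg C m^-3 (loess deposit), stocks Pg C (1 Pg = 1e12 kg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atmosphere import change_uncertainty, combine_errors, cov
from .world import BIOME_CLASSES, PeatCurves

KG_TO_PG = 1e-12

POOLS = (
    "mineral_land",
    "mineral_exposed_shelf",
    "mineral_inundated",
    "peat",
    "loess_deep",
    "subglacial",
    "postglacial_accruing",
)


class LedgerError(ValueError):
    """A bookkeeping precondition failed (usually an upstream bug)."""


# ---------------------------------------------------------------------------
# transfer functions


def _default_densities() -> dict:
    """Typical biome soil C densities, kg C m^-2 over 0-2 m, (mean, sd),
    keyed by (class, permafrost-state)."""
    base = {
        "tundra": ((40.0, 12.0), (22.0, 8.0)),
        "boreal forest": ((25.0, 8.0), (15.0, 5.0)),
        "temperate forest": ((18.0, 6.0), (12.0, 4.0)),
        "warm-temperate forest": ((10.0, 3.0), (9.0, 3.0)),
        "tropical forest": ((8.0, 3.0), (8.0, 3.0)),
        "grassland/dry shrubland": ((15.0, 5.0), (10.0, 3.0)),
        "savanna/dry woodland": ((7.0, 2.0), (6.0, 2.0)),
        "desert": ((3.0, 1.5), (3.0, 1.5)),
    }
    out = {}
    for cls, (pf, nopf) in base.items():
        out[(cls, "permafrost")] = pf
        out[(cls, "no-permafrost")] = nopf
    return out


@dataclass
class TransferFunctionTable:
    """Biome x permafrost-state soil C densities plus the alpine slope rule.

    Steep-slope area fractions bypass the biome lookup and carry a fixed
    3 kg C m^-2.
    """

    densities: dict = field(default_factory=_default_densities)
    slope_density_kg_m2: float = 3.0
    slope_sd_kg_m2: float = 1.5
    slope_threshold_deg: float = 4.0

    def validate(self) -> None:
        for cls in BIOME_CLASSES:
            for state in ("permafrost", "no-permafrost"):
                if (cls, state) not in self.densities:
                    raise LedgerError(f"transfer function missing for ({cls}, {state})")
                m, sd = self.densities[(cls, state)]
                if m < 0 or sd < 0:
                    raise LedgerError(f"negative density for ({cls}, {state})")

    def vectors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(mean_pf, mean_nopf, sd_pf, sd_nopf) ordered like BIOME_CLASSES."""
        self.validate()
        m_pf = np.array([self.densities[(c, "permafrost")][0] for c in BIOME_CLASSES])
        m_np = np.array([self.densities[(c, "no-permafrost")][0] for c in BIOME_CLASSES])
        s_pf = np.array([self.densities[(c, "permafrost")][1] for c in BIOME_CLASSES])
        s_np = np.array([self.densities[(c, "no-permafrost")][1] for c in BIOME_CLASSES])
        return m_pf, m_np, s_pf, s_np


# ---------------------------------------------------------------------------
# state containers


@dataclass
class CarbonState:
    """Per-millennium stocks: (mean, sd) per pool plus per-cell maps (Pg)."""

    time: int
    pools: dict  # pool -> (mean_pgc, sd_pgc)
    mineral_map: np.ndarray | None = None  # mineral + accruing, incl. shelf
    peat_map: np.ndarray | None = None

    @property
    def total(self) -> float:
        return float(sum(m for m, _ in self.pools.values()))

    def total_map(self) -> np.ndarray:
        return self.mineral_map + self.peat_map


@dataclass
class FluxRecord:
    """Net change decomposition between two consecutive millennia.

    ``cycled_flux_pgc`` is carbon remobilised through the atmosphere at
    inundation; it adds to the loss side of the net change without moving
    any stock.  Losses are negative.
    """

    t_old: int
    t_young: int
    pool_deltas: dict  # pool -> Pg C
    cycled_flux_pgc: float
    net_to_atmosphere_pgc: float
    net_uncertainty_pgc: float
    pool_uncertainties: dict = field(default_factory=dict)

    @property
    def total_stock_delta(self) -> float:
        return float(sum(self.pool_deltas.values()))


# ---------------------------------------------------------------------------
# mineral soils


def mineral_stock(
    fractions: np.ndarray,
    tf: TransferFunctionTable,
    pf_continuous: np.ndarray,
    peat_frac: np.ndarray,
    slope_frac: np.ndarray,
    cell_area: np.ndarray,
    land_mask: np.ndarray,
    shelf_mask: np.ndarray,
    accrual_age: np.ndarray | None = None,
    accrual_density: np.ndarray | None = None,
) -> dict:
    """Per-cell mineral soil stock and its split into pools.

    Cell stock = area * [(1 - peat_frac - slope_frac) * sum_c frac_c *
    tf(c, state) + slope_frac * slope_density]; the permafrost state is the
    continuous-permafrost delineation.  Cells within three millennia of
    deglaciation use the supplied accrual density instead of the biome
    lookup and are booked to the ``postglacial_accruing`` pool.  Stocks are
    assumed in equilibrium with their biome within each millennium.
    """
    over = land_mask & (peat_frac + slope_frac > 1 + 1e-9)
    if np.any(over):
        iy, ix = np.argwhere(over)[0]
        raise LedgerError(f"peat+slope fractions exceed 1 at cell ({iy}, {ix})")
    m_pf, m_np, s_pf, s_np = tf.vectors()

    tf_mean = np.where(pf_continuous, m_pf[:, None, None], m_np[:, None, None])
    d_biome = np.einsum("cij,cij->ij", fractions, tf_mean)
    avail = np.clip(1.0 - peat_frac - slope_frac, 0.0, 1.0)
    density = avail * d_biome + slope_frac * tf.slope_density_kg_m2

    accruing = np.zeros_like(land_mask)
    if accrual_age is not None:
        accruing = land_mask & np.isfinite(accrual_age) & (accrual_age <= 3)
        if accrual_density is None:
            raise LedgerError("accrual ages supplied without accrual densities")
        density = np.where(
            accruing,
            avail * accrual_density + slope_frac * tf.slope_density_kg_m2,
            density,
        )

    stock_map = np.where(land_mask, density * cell_area * KG_TO_PG, 0.0)

    land_only = land_mask & ~shelf_mask & ~accruing
    shelf_only = land_mask & shelf_mask & ~accruing

    def _pool(mask: np.ndarray) -> tuple[float, float]:
        total = float(stock_map[mask].sum())
        # tf errors are systematic within a (class, state): exposures add
        # linearly per class, classes combine by root-sum-of-variances
        w = np.where(mask, avail * cell_area, 0.0)
        var = 0.0
        for state, sd_vec in ((pf_continuous, s_pf), (~pf_continuous, s_np)):
            exp_c = np.einsum("cij,ij->c", fractions, np.where(state, w, 0.0))
            var += float(np.sum((exp_c * sd_vec) ** 2))
        slope_exp = float((slope_frac * cell_area)[mask].sum())
        var += (slope_exp * tf.slope_sd_kg_m2) ** 2
        return total, np.sqrt(var) * KG_TO_PG

    land_total, land_sd = _pool(land_only)
    shelf_total, shelf_sd = _pool(shelf_only)
    acc_total = float(stock_map[accruing].sum())
    acc_sd = 0.3 * acc_total  # young accruing soils: broad 30% relative SD
    return {
        "map": stock_map,
        "mineral_land": (land_total, land_sd),
        "mineral_exposed_shelf": (shelf_total, shelf_sd),
        "postglacial_accruing": (acc_total, acc_sd),
        "accruing_mask": accruing,
    }


def average_models(result_a: dict, result_b: dict) -> dict:
    """Arithmetic mean of two single-model mineral results.

    The inter-model gap is retained as a diagnostic, reported per pool as a
    percentage of the (averaged) pool SD.
    """
    if result_a["map"].shape != result_b["map"].shape:
        raise LedgerError("model grids do not match")
    out = {"map": 0.5 * (result_a["map"] + result_b["map"])}
    gaps = {}
    for pool in ("mineral_land", "mineral_exposed_shelf", "postglacial_accruing"):
        ma, sa = result_a[pool]
        mb, sb = result_b[pool]
        mean, sd = 0.5 * (ma + mb), 0.5 * (sa + sb)
        out[pool] = (mean, sd)
        gaps[pool] = abs(ma - mb) / sd * 100.0 if sd > 0 else 0.0
    out["accruing_mask"] = result_a["accruing_mask"] | result_b["accruing_mask"]
    out["intermodel_gap_pct_of_sd"] = gaps
    return out


# ---------------------------------------------------------------------------
# loess


def loess_step(
    region_state: dict,
    frozen_frac_old: dict,
    frozen_frac_new: dict,
    deposition_pgc: dict | None = None,
    retention_on_thaw: float = 0.1,
) -> tuple[dict, dict]:
    """Advance per-region deep-loess stocks by one millennium.

    ``region_state`` maps region name to {"frozen": Pg, "thawed": Pg};
    ``frozen_frac_*`` give the fraction of each region inside continuous
    permafrost (already averaged over the two climate models).  The frozen
    stock thawing this millennium loses (1 - retention) of its carbon within
    the millennium of thaw; the retained remainder moves to the thawed
    stock.  Deposition (the 21-17 ka syngenetic accumulation) adds to the
    frozen stock.  Returns (new_state, loss_per_region).
    """
    if not (0 <= retention_on_thaw <= 1):
        raise LedgerError("retention on thaw must be in [0, 1]")
    new_state, losses = {}, {}
    for region, st in region_state.items():
        frozen, thawed = st["frozen"], st["thawed"]
        if frozen < -1e-9 or thawed < -1e-9:
            raise LedgerError(f"negative loess stock in region {region}")
        if deposition_pgc:
            frozen += deposition_pgc.get(region, 0.0)
        f_old = frozen_frac_old.get(region, 0.0)
        f_new = frozen_frac_new.get(region, 0.0)
        thaw_of_frozen = max(0.0, (f_old - f_new) / f_old) if f_old > 0 else 0.0
        moved = frozen * thaw_of_frozen
        frozen -= moved
        thawed += moved * retention_on_thaw
        losses[region] = moved * (1.0 - retention_on_thaw)
        new_state[region] = {"frozen": frozen, "thawed": thawed}
    return new_state, losses


def loess_anchor_trajectory(anchors: dict, times) -> np.ndarray:
    """Total deep-loess stock interpolated between isochrone anchors.

    The chronological control of the loess sections is reduced to linear
    interpolation of the regional (here: total) stock between configured
    anchor points {ka: Pg C}.
    """
    t = np.asarray(sorted(anchors))
    v = np.asarray([anchors[k] for k in sorted(anchors)])
    return np.interp(np.asarray(times, dtype=float), t, v)


DEFAULT_LOESS_ANCHORS = {
    # 363 Pg at 21 ka rising through syngenetic deposition to the 398 Pg
    # peak at 17 ka, then thaw-driven decline shaped to the reconstruction's
    # per-millennium losses (42 Pg 17-16 ka, 49 Pg 15-14 ka, 88 Pg 12-11 ka)
    # down to the 57 Pg remaining at preindustrial.
    21: 363.0,
    17: 398.0,
    16: 356.0,
    15: 330.0,
    14: 281.0,
    13: 250.0,
    12: 220.0,
    11: 132.0,
    10: 95.0,
    9: 80.0,
    8: 70.0,
    7: 62.0,
    6: 60.0,
    5: 58.0,
    0: 57.0,
}


def loess_region_sd(table_row) -> float:
    """First-order relative SD of a region's stock from independent area,
    depth and density variances."""
    return float(
        np.sqrt(
            table_row["area_sd_frac"] ** 2
            + table_row["depth_sd_frac"] ** 2
            + table_row["density_sd_frac"] ** 2
        )
    )


# ---------------------------------------------------------------------------
# peat


PEAT_EXTENT_SD_FRAC = 0.10
PEAT_STOCK_SD_FRAC = 0.36
PEAT_RAMP_MAX = 0.50
PEAT_RAMP_AGE = 16.0


def peat_uncertainty_frac(t: float) -> float:
    """Relative peat-stock SD: present-day extent and stock uncertainties
    combined (root-sum-of-variances) with a back-in-time ramp growing
    linearly from 0 at PI to +/-50% at 16 ka."""
    ramp = PEAT_RAMP_MAX * min(t, PEAT_RAMP_AGE) / PEAT_RAMP_AGE
    return float(np.sqrt(PEAT_EXTENT_SD_FRAC**2 + PEAT_STOCK_SD_FRAC**2 + ramp**2))


def peat_step(
    curves: PeatCurves,
    t: int,
    land_mask: np.ndarray,
    peat_init: np.ndarray,
    peat_pi_frac: np.ndarray,
    cell_area: np.ndarray,
) -> dict:
    """Distribute the millennium's peat stock and area across the grid.

    The pool total is pi_total_stock * stock_fraction(t).  Area goes to
    cells already initiated by t (initiation age >= t), proportionally to
    their PI peat extent, scaled so the summed area equals pi_total_area *
    area_fraction(t); no cell exceeds its PI extent before the final step.
    Returns the stock map (Pg), the per-cell peat area fraction, the pool
    total and its SD.
    """
    total = curves.pi_total_stock_pgc * curves.stock_at(t)
    target_area = curves.pi_total_area_km2 * 1e6 * curves.area_at(t)
    eligible = land_mask & np.isfinite(peat_init) & (peat_init >= t) & (peat_pi_frac > 0)
    if target_area > 0 and not np.any(eligible):
        raise LedgerError(f"no eligible peat cells at {t} ka but area fraction > 0")
    peat_area = np.zeros_like(cell_area)
    if target_area > 0:
        cap = np.where(eligible, peat_pi_frac * cell_area, 0.0)
        w = cap.copy()
        # proportional fill with a per-cell cap at the PI extent; a couple of
        # passes redistribute any clipped surplus
        remaining = target_area
        for _ in range(4):
            wsum = w.sum()
            if wsum <= 0 or remaining <= 1e-6 * target_area:
                break
            add = np.minimum(w / wsum * remaining, cap - peat_area)
            peat_area += add
            remaining -= float(add.sum())
            w = np.where(peat_area < cap, cap - peat_area, 0.0)
    area_sum = float(peat_area.sum())
    stock_map = peat_area / area_sum * total if area_sum > 0 else np.zeros_like(peat_area)
    frac = np.divide(peat_area, cell_area, out=np.zeros_like(peat_area), where=cell_area > 0)
    return {
        "map": stock_map,
        "frac": frac,
        "peat": (total, total * peat_uncertainty_frac(t)),
    }


# ---------------------------------------------------------------------------
# post-glacial accrual


ACCRUAL_K_PER_KA = {
    "tundra": 1.1,
    "boreal forest": 1.1,
    "temperate forest": 1.1,
    "warm-temperate forest": 1.1,
    "tropical forest": 1.1,
    "grassland/dry shrubland": 0.5,
    "savanna/dry woodland": 0.5,
    "desert": 0.5,
}


def postglacial_accrual(
    time_since_deglaciation_ka: float,
    biome_class: str,
    ce_0_1_kg_m2: float,
    ce_1_2_kg_m2: float,
    k_per_ka: float | None = None,
) -> float:
    """Soil C density (kg m^-2) accrued since deglaciation.

    Exponential approach to the biome's equilibrium C: C(t) = Ce (1 -
    exp(-k t)).  Default rate constants bring forest and tundra soils to
    >= 95% of equilibrium within the three-millennium accrual window;
    grassland-type soils deliberately fall short.
    """
    if biome_class not in ACCRUAL_K_PER_KA:
        raise LedgerError(f"unknown biome class {biome_class!r}")
    k = ACCRUAL_K_PER_KA[biome_class] if k_per_ka is None else k_per_ka
    ce = ce_0_1_kg_m2 + ce_1_2_kg_m2
    return float(ce * (1.0 - np.exp(-k * time_since_deglaciation_ka)))


def accrual_density_map(
    fractions: np.ndarray,
    tf: TransferFunctionTable,
    pf_continuous: np.ndarray,
    age_ka: np.ndarray,
) -> np.ndarray:
    """Fraction-weighted accrual density for cells in the accrual window."""
    m_pf, m_np, _, _ = tf.vectors()
    ce = np.where(pf_continuous, m_pf[:, None, None], m_np[:, None, None])
    k = np.array([ACCRUAL_K_PER_KA[c] for c in BIOME_CLASSES])
    age = np.where(np.isfinite(age_ka), np.clip(age_ka, 0.0, None), 0.0)
    growth = 1.0 - np.exp(-k[:, None, None] * age[None])
    return np.einsum("cij,cij->ij", fractions, ce * growth)


# ---------------------------------------------------------------------------
# subglacial and shelf


TUNDRA_PF_DENSITY_KG_M2 = 40.0
TUNDRA_PF_SD_KG_M2 = 12.0
PEAT_1M_DENSITY_KG_M2 = 50.0
PEAT_1M_SD_KG_M2 = 25.0
SUBGLACIAL_PEAT_SHARE = 0.01


def subglacial_stock(
    area_m2: float,
    tundra_density: float = TUNDRA_PF_DENSITY_KG_M2,
    tundra_sd: float = TUNDRA_PF_SD_KG_M2,
    peat1m_density: float = PEAT_1M_DENSITY_KG_M2,
    peat1m_sd: float = PEAT_1M_SD_KG_M2,
    peat_share: float = SUBGLACIAL_PEAT_SHARE,
) -> tuple[float, float]:
    """Carbon preserved beneath cold-based ice: a high-arctic tundra soil
    across the whole area plus 1 m of peat across 1% of it.  (mean, sd) Pg."""
    mean = area_m2 * (tundra_density + peat_share * peat1m_density) * KG_TO_PG
    sd = area_m2 * np.hypot(tundra_sd, peat_share * peat1m_sd) * KG_TO_PG
    return float(mean), float(sd)


def subglacial_step(
    area_old_m2: float,
    area_new_m2: float,
    allow_readvance: bool = False,
    **densities,
) -> tuple[tuple[float, float], float]:
    """New subglacial stock and the release to the atmosphere on retreat.

    Exposed subglacial carbon oxidises rapidly, so the stock difference is
    booked as an immediate loss.  Ice readvance is rejected unless the
    scenario explicitly permits it.
    """
    old, _ = subglacial_stock(area_old_m2, **densities)
    new_stock = subglacial_stock(area_new_m2, **densities)
    release = old - new_stock[0]
    if release < -1e-12 and not allow_readvance:
        raise LedgerError("ice readvance encountered but not permitted by scenario")
    return new_stock, float(release)


def shelf_transfer(
    land_old: np.ndarray,
    land_new: np.ndarray,
    land_pi: np.ndarray,
    stock_map_old: np.ndarray,
    cycling_fraction: float = 0.30,
    inundated_pool_old: float = 0.0,
) -> dict:
    """Move soil C from newly drowned shelf cells into the inundated pool.

    Total stock is conserved exactly (inundated C is assumed preserved in
    place); ``cycling_fraction`` of the transferred carbon is additionally
    recorded as a flux cycled through the atmosphere, counted in net
    changes only.
    """
    if not (0 <= cycling_fraction <= 0.66):
        raise LedgerError("cycling fraction outside the supported 0-0.66 range")
    shelf_old = land_old & ~land_pi
    shelf_new = land_new & ~land_pi
    if np.any(shelf_new & ~shelf_old):
        raise LedgerError("shelf cells re-emerged after inundation; not supported")
    newly_inundated = shelf_old & ~land_new
    transferred = float(stock_map_old[newly_inundated].sum())
    return {
        "transferred_pgc": transferred,
        "inundated_pool_pgc": inundated_pool_old + transferred,
        "cycled_flux_pgc": cycling_fraction * transferred,
        "newly_inundated": newly_inundated,
    }


# ---------------------------------------------------------------------------
# net and gross changes


CYCLED_SD_FRACTION = 0.5  # 30% central vs 0-66% range on the cycling share


def net_change(
    state_old: CarbonState,
    state_young: CarbonState,
    cycled_flux_pgc: float = 0.0,
) -> FluxRecord:
    """Millennial net change decomposition with propagated uncertainty.

    Per-pool uncertainties follow E = mean(V) * |delta| with V = sigma^2/mu
    evaluated where the pool exists; pools plus the cycled-flux error
    combine by root-sum-of-variances.  The net transfer to the atmosphere
    is the total stock delta minus the cycled flux (losses negative).
    """
    if state_old.time != state_young.time + 1:
        raise LedgerError(
            f"states {state_old.time} and {state_young.time} ka are not consecutive"
        )
    deltas, errors = {}, {}
    for pool in POOLS:
        m0, s0 = state_old.pools.get(pool, (0.0, 0.0))
        m1, s1 = state_young.pools.get(pool, (0.0, 0.0))
        delta = m1 - m0
        deltas[pool] = delta
        vs = [cov(s**2, m) for m, s in ((m0, s0), (m1, s1)) if m > 0]
        v = float(np.mean(vs)) if vs else 0.0
        errors[pool] = change_uncertainty(v, v, delta)
    e_cycled = abs(cycled_flux_pgc) * CYCLED_SD_FRACTION
    combined = combine_errors(list(errors.values()) + [e_cycled])
    total_delta = float(sum(deltas.values()))
    return FluxRecord(
        t_old=state_old.time,
        t_young=state_young.time,
        pool_deltas=deltas,
        cycled_flux_pgc=float(cycled_flux_pgc),
        net_to_atmosphere_pgc=total_delta - abs(cycled_flux_pgc),
        net_uncertainty_pgc=combined,
        pool_uncertainties=errors,
    )


def gross_changes(stock_map_old: np.ndarray, stock_map_young: np.ndarray) -> tuple[float, float]:
    """(gross gains, gross losses) in Pg C between two co-registered maps.

    Gains are the sum of positive per-cell deltas, losses of negative ones;
    gains + losses equal the net delta exactly.
    """
    if stock_map_old.shape != stock_map_young.shape:
        raise LedgerError("stock maps are not co-registered")
    diff = stock_map_young - stock_map_old
    return float(diff[diff > 0].sum()), float(diff[diff < 0].sum())
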