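"""Synthetic world generator.

Emulates every input the reconstruction consumes from climate models and
paleo databases, with known ground truth so downstream stages can be tested
by parameter recovery:

* two gridded millennial climate ensembles (pseudo-HadCM3 as the unbiased
  reference and pseudo-TraCE carrying a constant cold bias on MAAT, so the
  downstream +5 degC correction has something real to correct),
* ice-sheet retreat, cold-based ice, and shoreline chronologies,
* a deterministic "true" biome map derived from climate by explicit
  threshold rules,
* pollen-style training samples with label noise and a protected flag,
* loess region masks with frozen/thawed carbon densities,
* monotone peat area/stock accumulation curves plus a preindustrial peat
  extent map and initiation ages.

All randomness flows through one seeded generator; the same seed and
scenario reproduce the world bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .grid import GridDomain, make_domain

# Fixed mega-biome class ordering; argmax ties break toward the lower index.
BIOME_CLASSES = (
    "tundra",
    "boreal forest",
    "temperate forest",
    "warm-temperate forest",
    "tropical forest",
    "grassland/dry shrubland",
    "savanna/dry woodland",
    "desert",
)
NO_BIOME = -1

CLIMATE_VARS = ("maat", "t_warm", "t_cold", "t_range", "pr_ann", "pr_gs")

REFERENCE_MODEL = "pseudo-HadCM3"
BIASED_MODEL = "pseudo-TraCE"
MODELS = (REFERENCE_MODEL, BIASED_MODEL)

TIMES_KA = tuple(range(21, -1, -1))  # 21 ka -> 0 ka (preindustrial)


class InvalidScenarioError(ValueError):
    """Scenario parameters violate a structural precondition."""


class ConfigurationError(ValueError):
    """Rule tables or config files are inconsistent."""


# ---------------------------------------------------------------------------
# scenario parameters


@dataclass
class BiomeRules:
    """Deterministic decision list mapping climate space to the 8 classes.

    Rules are evaluated in order on every unglaciated land cell:
    desert (aridity), tundra (cold summers), open vegetation split by MAAT,
    then the forest classes by MAAT bands, with tropical forest as the
    warm-wet remainder.  The decision-list form guarantees the rule set is
    complete and non-overlapping; ``validate`` rejects incoherent thresholds.
    """

    desert_precip_mm: float = 140.0
    tundra_t_warm_c: float = 10.0
    open_precip_mm: float = 320.0
    savanna_maat_c: float = 13.0
    boreal_maat_c: float = 1.0
    temperate_maat_c: float = 11.0
    warm_temperate_maat_c: float = 17.0

    def validate(self) -> None:
        vals = dataclasses.astuple(self)
        if not all(np.isfinite(v) for v in vals):
            raise ConfigurationError("biome rule thresholds must be finite")
        if not (self.boreal_maat_c < self.temperate_maat_c < self.warm_temperate_maat_c):
            raise ConfigurationError(
                "forest MAAT thresholds must be strictly increasing "
                "(boreal < temperate < warm-temperate)"
            )
        if self.desert_precip_mm >= self.open_precip_mm:
            raise ConfigurationError("desert threshold must lie below the open/forest split")

    def classify(self, maat: np.ndarray, t_warm: np.ndarray, pr_ann: np.ndarray) -> np.ndarray:
        """Vectorised decision list; returns class codes into BIOME_CLASSES."""
        self.validate()
        out = np.full(maat.shape, BIOME_CLASSES.index("tropical forest"), dtype=np.int8)
        out[maat < self.warm_temperate_maat_c] = BIOME_CLASSES.index("warm-temperate forest")
        out[maat < self.temperate_maat_c] = BIOME_CLASSES.index("temperate forest")
        out[maat < self.boreal_maat_c] = BIOME_CLASSES.index("boreal forest")
        is_open = pr_ann < self.open_precip_mm
        out[is_open & (maat >= self.savanna_maat_c)] = BIOME_CLASSES.index("savanna/dry woodland")
        out[is_open & (maat < self.savanna_maat_c)] = BIOME_CLASSES.index("grassland/dry shrubland")
        out[t_warm < self.tundra_t_warm_c] = BIOME_CLASSES.index("tundra")
        out[pr_ann < self.desert_precip_mm] = BIOME_CLASSES.index("desert")
        return out


@dataclass
class LoessRegionSpec:
    """One loess sector: a lat/lon rectangle plus depth and C densities.

    ``depth_below_2m_m`` is the thickness of the deep (below 2 m) deposit
    and already includes the extra metre of original deposit added because
    biome stocks only cover 0-2 m.  Densities are kg C per m^3 of deposit;
    the thawed density must be strictly below the frozen (Yedoma-like) one.
    """

    name: str
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    depth_below_2m_m: float
    c_density_frozen_kg_m3: float
    c_density_thawed_kg_m3: float
    area_sd_frac: float = 0.05
    depth_sd_frac: float = 0.07
    density_sd_frac: float = 0.06


def default_loess_regions() -> list[LoessRegionSpec]:
    """Four sectors mirroring the US / Central Europe / Central Siberia /
    China geography; densities are later rescaled so the 21-ka stock equals
    the configured total."""
    return [
        LoessRegionSpec("united_states", -100, -88, 39, 44, 8.0, 16.0, 1.6),
        LoessRegionSpec("central_europe", 10, 30, 47, 51, 6.0, 16.0, 1.6),
        LoessRegionSpec("central_siberia", 95, 125, 62, 69, 18.0, 16.0, 1.6),
        LoessRegionSpec("china", 103, 113, 34, 39, 20.0, 16.0, 1.6),
    ]


@dataclass
class Scenario:
    """Every knob of the synthetic world.

    Temperatures in degC, precipitation in mm/yr, times in ka BP.  Defaults
    encode the study conditions: a ~9 degC high-latitude deglacial warming
    concentrated between 17 and 10 ka, a -5 degC systematic MAAT bias on the
    pseudo-TraCE ensemble, monotone ice retreat completing by 5 ka, shelf
    exposure of roughly the same area as the deglaciated gain, four loess
    regions summing to 363 Pg C at 21 ka, and peat curves reaching 450 Pg C
    at preindustrial from ~0 at 16 ka.
    """

    # climate
    t_south_pi_c: float = 20.0          # PI MAAT at the 23N edge
    lat_gradient_c_per_deg: float = 0.75
    lgm_cooling_c: float = 9.0          # domain-scale LGM-PI cooling amplitude
    polar_amplification: float = 0.8    # cooling scales 0.6x (south) .. 1.4x (north)
    seasonal_base_c: float = 14.0
    seasonal_polar_c: float = 12.0
    winter_asymmetry: float = 1.2       # t_cold = maat - asym * seasonal amp
    precip_south_mm: float = 950.0
    precip_efold_deg: float = 45.0
    dry_band_lat: float = 38.0
    dry_band_width_deg: float = 7.0
    dry_band_depth_mm: float = 620.0
    glacial_drying: float = 0.35        # fractional precip reduction at full glacial
    noise_temp_c: float = 1.5           # sd of the smooth spatial MAAT anomaly
    noise_precip_frac: float = 0.15
    noise_length_deg: float = 6.0
    model_bias_c: dict = field(
        default_factory=lambda: {REFERENCE_MODEL: 0.0, BIASED_MODEL: -5.0}
    )
    # deglacial warming weight w(t): 1 = full glacial, 0 = PI
    warming_anchors: dict = field(
        default_factory=lambda: {21: 1.0, 17: 1.0, 10: 0.15, 0: 0.0}
    )
    # geography
    na_lon: tuple = (-170.0, -55.0)
    eu_lon: tuple = (-10.0, 140.0)
    na_coast_lat: float = 70.0
    eu_coast_lat: float = 72.0
    greenland_lon: tuple = (-45.0, -20.0)
    greenland_lat_min: float = 60.0
    shelf_width_deg: float = 6.0
    shelf_max_depth_m: float = 120.0
    sea_level_anchors: dict = field(
        default_factory=lambda: {21: -120.0, 16: -100.0, 10: -30.0, 6: -5.0, 0: 0.0}
    )
    ice_sectors: tuple = ((-130.0, -55.0), (0.0, 60.0))
    # southern ice margin latitude per ka; must move north as t decreases
    ice_line_anchors: dict = field(
        default_factory=lambda: {21: 48.0, 16: 52.0, 13: 58.0, 10: 64.0, 8: 68.0, 6: 70.0, 5: 91.0}
    )
    cold_based_inset_deg: float = 1.0
    cold_based_width_deg: float = 3.0
    # biomes / training
    biome_rules: BiomeRules = field(default_factory=BiomeRules)
    n_per_slice: int = 500
    label_noise: float = 0.1
    protected_rate: float = 0.1
    # loess
    loess_regions: list = field(default_factory=default_loess_regions)
    loess_lgm_stock_pgc: float | None = 363.0   # rescale densities to hit this
    loess_deposition_pgc_per_ka: float = 8.75   # 21-17 ka, total across regions
    loess_deposition_end_ka: int = 17
    loess_retention_on_thaw: float = 0.1
    # peat
    peat_pi_stock_pgc: float = 450.0
    peat_pi_area_km2: float = 3.7e6
    peat_stock_mid_ka: float = 8.0
    peat_stock_scale_ka: float = 2.2
    peat_area_mid_ka: float = 9.0
    peat_area_scale_ka: float = 2.5
    peat_zero_age_ka: float = 16.0
    peat_south_rule_lat: float = 38.0
    peat_south_rule_init_ka: float = 12.0
    # topography
    elev_scale_m: float = 1800.0
    slope_max_frac: float = 0.35


# ---------------------------------------------------------------------------
# helpers


def _interp_anchor(anchors: dict, times: np.ndarray) -> np.ndarray:
    t = np.asarray(sorted(anchors))
    v = np.asarray([anchors[k] for k in sorted(anchors)])
    return np.interp(times, t, v)


def _smooth_noise(rng: np.random.Generator, domain: GridDomain, length_deg: float) -> np.ndarray:
    """Unit-variance smooth random field, periodic in longitude."""
    white = rng.standard_normal(domain.shape)
    sigma = max(length_deg / domain.resolution, 1e-6)
    f = gaussian_filter(white, sigma=sigma, mode=("nearest", "wrap"))
    sd = f.std()
    return f / sd if sd > 0 else f


def _lon_window(lon: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (lon >= lo) & (lon < hi)


def _interior_weight(domain: GridDomain, scenario: Scenario) -> np.ndarray:
    """Continentality weight in [0,1], peaking mid-continent."""
    lon = domain.lon2d()
    w = np.zeros(domain.shape)
    for lo, hi in (scenario.na_lon, scenario.eu_lon):
        inside = _lon_window(lon, lo, hi)
        c, width = 0.5 * (lo + hi), hi - lo
        bump = np.cos(np.pi * (lon - c) / width) ** 2
        w = np.where(inside, np.maximum(w, bump), w)
    return w


# ---------------------------------------------------------------------------
# climate


def simulate_climate(
    domain: GridDomain, scenario: Scenario, seed: int
) -> dict[str, xr.Dataset]:
    """Generate the two millennial climate ensembles.

    Both share one warming trajectory and one smooth spatial anomaly; the
    biased ensemble differs by a constant MAAT offset (applied to all
    temperature fields so internal consistency holds).  Deterministic given
    the seed.
    """
    if seed is None:
        raise InvalidScenarioError("a seed is required: runs must be reproducible")
    rng = np.random.default_rng(seed)
    lat2 = domain.lat2d()
    times = np.asarray(TIMES_KA, dtype=float)

    t_anom = scenario.noise_temp_c * _smooth_noise(rng, domain, scenario.noise_length_deg)
    p_anom = scenario.noise_precip_frac * _smooth_noise(rng, domain, scenario.noise_length_deg)

    frac_north = (lat2 - 23.0) / 67.0
    maat0 = (
        scenario.t_south_pi_c
        - scenario.lat_gradient_c_per_deg * (lat2 - 23.0)
        + t_anom
    )
    amp = (1.0 - scenario.polar_amplification / 2.0) + scenario.polar_amplification * frac_north
    seas = scenario.seasonal_base_c + scenario.seasonal_polar_c * frac_north

    interior = _interior_weight(domain, scenario)
    dry = scenario.dry_band_depth_mm * interior * np.exp(
        -(((lat2 - scenario.dry_band_lat) / scenario.dry_band_width_deg) ** 2)
    )
    precip0 = (
        scenario.precip_south_mm * np.exp(-(lat2 - 23.0) / scenario.precip_efold_deg) - dry
    ) * (1.0 + p_anom)
    gs_frac = np.clip(0.75 - 0.45 * frac_north, 0.15, 0.75)

    w = _interp_anchor(scenario.warming_anchors, times)

    out: dict[str, xr.Dataset] = {}
    for model in MODELS:
        bias = scenario.model_bias_c[model]
        maat = maat0[None] - scenario.lgm_cooling_c * w[:, None, None] * amp[None] + bias
        t_warm = maat + seas[None]
        t_cold = maat - scenario.winter_asymmetry * seas[None]
        pr_ann = np.clip(
            precip0[None] * (1.0 - scenario.glacial_drying * w[:, None, None]), 0.0, None
        )
        pr_gs = pr_ann * gs_frac[None]
        out[model] = xr.Dataset(
            {
                "maat": (("time", "lat", "lon"), maat),
                "t_warm": (("time", "lat", "lon"), t_warm),
                "t_cold": (("time", "lat", "lon"), t_cold),
                "t_range": (("time", "lat", "lon"), t_warm - t_cold),
                "pr_ann": (("time", "lat", "lon"), pr_ann),
                "pr_gs": (("time", "lat", "lon"), pr_gs),
            },
            coords={"time": list(TIMES_KA), "lat": domain.lat, "lon": domain.lon},
            attrs={"model": model, "bias_c": bias},
        )
    return out


# ---------------------------------------------------------------------------
# ice, sea level, land


def simulate_ice_and_sea(domain: GridDomain, scenario: Scenario, seed: int) -> xr.Dataset:
    """Ice / cold-based / land mask chronologies.

    Ice retreats monotonically poleward in two sectors, finishing by 5 ka
    (a Greenland-analogue residual persists); cold-based ice is the retreating
    interior, inset poleward of the margin.  Shelf cells carry a bathymetry
    proportional to distance from the modern coast and drown as sea level
    rises from -120 m to 0.  ``land + ice + ocean`` partitions the domain.
    """
    if seed is None:
        raise InvalidScenarioError("a seed is required: runs must be reproducible")
    times = np.asarray(TIMES_KA, dtype=float)
    line = _interp_anchor(scenario.ice_line_anchors, times)
    if np.any(np.diff(line) < 0):  # times descend 21->0, margin must move north
        raise InvalidScenarioError("ice retreat schedule is not monotone")
    sl = _interp_anchor(scenario.sea_level_anchors, times)
    if np.any(np.diff(sl) < 0):
        raise InvalidScenarioError("sea level must be non-decreasing from 21 ka to 0 ka")

    lat2, lon2 = domain.lat2d(), domain.lon2d()

    base_land = np.zeros(domain.shape, dtype=bool)
    depth = np.full(domain.shape, np.nan)  # bathymetry of shelf cells, m
    for lon_rng, coast in (
        (scenario.na_lon, scenario.na_coast_lat),
        (scenario.eu_lon, scenario.eu_coast_lat),
    ):
        sector = _lon_window(lon2, *lon_rng)
        base_land |= sector & (lat2 < coast)
        shelf = sector & (lat2 >= coast) & (lat2 < coast + scenario.shelf_width_deg)
        d = scenario.shelf_max_depth_m * (lat2 - coast + domain.resolution) / scenario.shelf_width_deg
        depth = np.where(shelf, d, depth)
    greenland = (
        _lon_window(lon2, *scenario.greenland_lon) & (lat2 >= scenario.greenland_lat_min)
    )
    base_land |= greenland

    ice_sector = np.zeros(domain.shape, dtype=bool)
    for lo, hi in scenario.ice_sectors:
        ice_sector |= _lon_window(lon2, lo, hi)

    nt = len(TIMES_KA)
    ice = np.zeros((nt, *domain.shape), dtype=bool)
    cold = np.zeros_like(ice)
    land = np.zeros_like(ice)
    for i in range(nt):
        retreating = ice_sector & (lat2 >= line[i]) & base_land & ~greenland
        ice_i = retreating | greenland
        cold[i] = (
            retreating
            & (lat2 >= line[i] + scenario.cold_based_inset_deg)
            & (lat2 < line[i] + scenario.cold_based_inset_deg + scenario.cold_based_width_deg)
        )
        exposed = ~np.isnan(depth) & (depth <= -sl[i])
        land[i] = (base_land | exposed) & ~ice_i
        ice[i] = ice_i
    return xr.Dataset(
        {
            "ice": (("time", "lat", "lon"), ice),
            "cold_based": (("time", "lat", "lon"), cold),
            "land": (("time", "lat", "lon"), land),
            "base_land": (("lat", "lon"), base_land),
        },
        coords={"time": list(TIMES_KA), "lat": domain.lat, "lon": domain.lon},
    )


def deglaciation_time(ice: xr.DataArray) -> np.ndarray:
    """Per-cell ka of first ice-free slice after being glaciated (NaN if
    never glaciated or never freed)."""
    arr = ice.values  # (time, lat, lon), time 21->0
    times = np.asarray(ice["time"].values, dtype=float)
    out = np.full(arr.shape[1:], np.nan)
    ever = arr.any(axis=0)
    for i in range(1, arr.shape[0]):
        newly_free = arr[i - 1] & ~arr[i] & np.isnan(out)
        out[newly_free] = times[i]
    out[~ever] = np.nan
    return out


# ---------------------------------------------------------------------------
# biomes and training samples


def simulate_true_biomes(
    climate: xr.Dataset, land: xr.DataArray, rules: BiomeRules
) -> xr.DataArray:
    """Deterministic true biome map from the reference climate.

    Every unglaciated land cell gets exactly one of the 8 classes; ice and
    ocean cells get ``NO_BIOME``.
    """
    codes = rules.classify(
        climate["maat"].values, climate["t_warm"].values, climate["pr_ann"].values
    )
    codes = np.where(land.values, codes, NO_BIOME).astype(np.int8)
    return xr.DataArray(
        codes, coords=climate["maat"].coords, dims=climate["maat"].dims, name="biome_true"
    )


def sample_pollen_sites(
    world: "World",
    n_per_slice: int,
    label_noise: float,
    protected_rate: float,
    seed: int,
    times: tuple[int, ...] = TIMES_KA,
) -> pd.DataFrame:
    """Draw pollen-style training points from the true biome map.

    Sites are drawn with replacement (duplicates are a feature of the real
    training compilation); a fraction ``label_noise`` get a wrong label
    uniform over the other 7 classes, and ``protected_rate`` are flagged
    protected (the analogue of entries exempt from training hygiene).
    """
    if n_per_slice < 1:
        raise InvalidScenarioError("n_per_slice must be >= 1")
    rng = np.random.default_rng(seed)
    ref = world.climates[REFERENCE_MODEL]
    elev = world.truth["elev"].values
    rows = []
    site_id = 0
    for t in times:
        biome = world.truth["biome_true"].sel(time=t).values
        eligible = np.flatnonzero(biome.ravel() >= 0)
        if eligible.size == 0:
            raise InvalidScenarioError(f"no unglaciated land cells to sample at {t} ka")
        picks = rng.choice(eligible, size=n_per_slice, replace=True)
        iy, ix = np.unravel_index(picks, biome.shape)
        labels = biome[iy, ix].astype(int)
        flip = rng.random(n_per_slice) < label_noise
        offset = rng.integers(1, len(BIOME_CLASSES), size=n_per_slice)
        labels = np.where(flip, (labels + offset) % len(BIOME_CLASSES), labels)
        protected = rng.random(n_per_slice) < protected_rate
        clim = ref.sel(time=t)
        for j in range(n_per_slice):
            rows.append(
                {
                    "site_id": site_id,
                    "lon": world.domain.lon[ix[j]],
                    "lat": world.domain.lat[iy[j]],
                    "time_ka": t,
                    "biome": BIOME_CLASSES[labels[j]],
                    "protected": bool(protected[j]),
                    **{v: float(clim[v].values[iy[j], ix[j]]) for v in CLIMATE_VARS},
                    "elev": float(elev[iy[j], ix[j]]),
                }
            )
            site_id += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# loess


def make_loess_regions(
    domain: GridDomain,
    specs: list[LoessRegionSpec],
    base_land: np.ndarray,
    calibrate_total_pgc: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterise loess regions and tabulate their implied deep-C stocks.

    Returns the region-id map (-1 outside) and a per-region table with areas
    (m^2), depths, densities, SDs and the implied frozen stock in Pg C.  If
    ``calibrate_total_pgc`` is set, frozen and thawed densities are rescaled
    by a common factor so the summed 21-ka stock equals that total exactly.
    """
    lat2, lon2 = domain.lat2d(), domain.lon2d()
    region_id = np.full(domain.shape, -1, dtype=np.int16)
    recs = []
    for i, s in enumerate(specs):
        if s.c_density_thawed_kg_m3 >= s.c_density_frozen_kg_m3:
            raise InvalidScenarioError(
                f"loess region {s.name}: thawed density must be < frozen density"
            )
        mask = (
            _lon_window(lon2, s.lon_min, s.lon_max)
            & (lat2 >= s.lat_min)
            & (lat2 < s.lat_max)
            & base_land
        )
        region_id[mask] = i
        area = float(domain.cell_area[mask].sum())
        recs.append(
            {
                "region_id": i,
                "name": s.name,
                "area_m2": area,
                "depth_m": s.depth_below_2m_m,
                "rho_frozen": s.c_density_frozen_kg_m3,
                "rho_thawed": s.c_density_thawed_kg_m3,
                "area_sd_frac": s.area_sd_frac,
                "depth_sd_frac": s.depth_sd_frac,
                "density_sd_frac": s.density_sd_frac,
            }
        )
    table = pd.DataFrame(recs)
    if len(table):
        stock = table["area_m2"] * table["depth_m"] * table["rho_frozen"] / 1e12  # kg -> Pg
        if calibrate_total_pgc is not None:
            total = float(stock.sum())
            if total <= 0:
                raise InvalidScenarioError("cannot calibrate zero loess stock")
            scale = calibrate_total_pgc / total
            table["rho_frozen"] *= scale
            table["rho_thawed"] *= scale
            stock = stock * scale
        table["stock_frozen_pgc"] = stock
    else:
        table["stock_frozen_pgc"] = []
    return region_id, table


# ---------------------------------------------------------------------------
# peat


@dataclass(frozen=True)
class PeatCurves:
    """Monotone peat area- and stock-fraction curves plus PI totals.

    Both fractions are ~0 at and before ``zero_age`` (default 16 ka, peat
    being rare during the glacial) and exactly 1 at 0 ka.
    """

    times: np.ndarray
    area_fraction: np.ndarray
    stock_fraction: np.ndarray
    pi_total_stock_pgc: float
    pi_total_area_km2: float

    def stock_at(self, t: float) -> float:
        return float(np.interp(t, self.times[::-1], self.stock_fraction[::-1]))

    def area_at(self, t: float) -> float:
        return float(np.interp(t, self.times[::-1], self.area_fraction[::-1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ka": self.times,
                "area_fraction": self.area_fraction,
                "stock_fraction": self.stock_fraction,
            }
        )


def _ramp_curve(times: np.ndarray, mid: float, scale: float, zero_age: float) -> np.ndarray:
    """Normalised logistic accumulation curve: 0 at zero_age, 1 at 0 ka."""
    from scipy.special import expit

    raw = expit((mid - times) / scale)
    lo = expit((mid - zero_age) / scale)
    hi = expit(mid / scale)
    f = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
    f[times >= zero_age] = 0.0
    return f


def make_peat_curves(scenario: Scenario) -> PeatCurves:
    """Build the accumulation curves from the scenario's shape parameters."""
    if scenario.peat_pi_stock_pgc <= 0:
        raise InvalidScenarioError("PI peat stock must be positive")
    if scenario.peat_stock_scale_ka <= 0 or scenario.peat_area_scale_ka <= 0:
        raise InvalidScenarioError("peat curve scales must be positive (monotone curves)")
    times = np.asarray(TIMES_KA, dtype=float)
    stock = _ramp_curve(
        times, scenario.peat_stock_mid_ka, scenario.peat_stock_scale_ka, scenario.peat_zero_age_ka
    )
    area = _ramp_curve(
        times, scenario.peat_area_mid_ka, scenario.peat_area_scale_ka, scenario.peat_zero_age_ka
    )
    return PeatCurves(
        times=times,
        area_fraction=area,
        stock_fraction=stock,
        pi_total_stock_pgc=scenario.peat_pi_stock_pgc,
        pi_total_area_km2=scenario.peat_pi_area_km2,
    )


def apply_peat_initiation_rule(
    init: np.ndarray, lat2: np.ndarray, south_lat: float = 38.0, fill_ka: float = 12.0
) -> np.ndarray:
    """Cells south of ``south_lat`` lacking initiation data get ``fill_ka``."""
    out = init.copy()
    missing = np.isnan(out) & (lat2 < south_lat)
    out[missing] = fill_ka
    return out


# ---------------------------------------------------------------------------
# full world


@dataclass
class World:
    """The complete synthetic study system: grid, climates, and truth."""

    domain: GridDomain
    scenario: Scenario
    seed: int
    climates: dict[str, xr.Dataset]
    truth: xr.Dataset  # biome_true, ice, cold_based, land + static fields
    loess_table: pd.DataFrame
    peat_curves: PeatCurves
    deglac_time: np.ndarray  # (lat, lon), ka of first ice-free slice

    @property
    def times(self) -> tuple[int, ...]:
        return TIMES_KA

    def land(self, t: int) -> np.ndarray:
        return self.truth["land"].sel(time=t).values

    def shelf(self, t: int) -> np.ndarray:
        """Exposed-shelf cells: land at t but not land at present."""
        return self.land(t) & ~self.land(0)

    def save(self, outdir: str | Path) -> None:
        """NetCDF for gridded fields, CSV for curves and the loess table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ds = self.truth.copy()
        for model, clim in self.climates.items():
            suffix = "_ref" if model == REFERENCE_MODEL else "_biased"
            for v in CLIMATE_VARS:
                ds[v + suffix] = clim[v]
        enc = {
            v: {"dtype": "int8"}
            for v in ("ice", "cold_based", "land", "base_land")
        }
        ds.to_netcdf(outdir / "world.nc", engine="scipy", encoding=enc)
        self.peat_curves.to_frame().to_csv(outdir / "peat_curves.csv", index=False)
        self.loess_table.to_csv(outdir / "loess_regions.csv", index=False)


def build_world(scenario: Scenario | None = None, seed: int = 0, resolution: float = 1.0) -> World:
    """Assemble the full synthetic world deterministically from seed+scenario."""
    scenario = scenario or Scenario()
    scenario.biome_rules.validate()
    domain = make_domain(resolution)
    rng = np.random.default_rng(seed)
    # independent sub-seeds so stages can be regenerated in isolation
    seeds = rng.integers(0, 2**31 - 1, size=4)

    climates = simulate_climate(domain, scenario, int(seeds[0]))
    masks = simulate_ice_and_sea(domain, scenario, int(seeds[1]))
    biome_true = simulate_true_biomes(
        climates[REFERENCE_MODEL], masks["land"], scenario.biome_rules
    )

    lat2 = domain.lat2d()
    interior = _interior_weight(domain, scenario)
    topo_rng = np.random.default_rng(int(seeds[2]))
    elev = (
        scenario.elev_scale_m * interior * np.exp(-(((lat2 - 42.0) / 9.0) ** 2))
        + 300.0 * np.abs(_smooth_noise(topo_rng, domain, scenario.noise_length_deg))
    )
    gy, gx = np.gradient(elev)
    slope_raw = np.hypot(gy, gx)
    peak = slope_raw.max()
    slope_frac = scenario.slope_max_frac * slope_raw / peak if peak > 0 else slope_raw

    base_land = masks["base_land"].values
    loess_id, loess_table = make_loess_regions(
        domain, scenario.loess_regions, base_land, scenario.loess_lgm_stock_pgc
    )

    peat_curves = make_peat_curves(scenario)
    land0 = masks["land"].sel(time=0).values
    ice0 = masks["ice"].sel(time=0).values
    pr0 = climates[REFERENCE_MODEL]["pr_ann"].sel(time=0).values
    pi_frac = (
        0.6
        * np.exp(-(((lat2 - 58.0) / 9.0) ** 2))
        * np.clip(pr0 / 700.0, 0.0, 1.0)
        * land0
        * ~ice0
    )
    pi_frac = np.minimum(pi_frac, 1.0 - slope_frac - 0.05)
    target = scenario.peat_pi_area_km2 * 1e6
    got = float((pi_frac * domain.cell_area).sum())
    if got <= 0:
        raise InvalidScenarioError("PI peat extent map is empty")
    pi_frac = np.clip(pi_frac * (target / got), 0.0, 0.9)
    # one rescale pass after the cap; residual mismatch is < 1e-6 relative
    pi_frac *= target / float((pi_frac * domain.cell_area).sum())

    dt = deglaciation_time(masks["ice"])
    init = np.where(np.isnan(dt), np.where(lat2 >= scenario.peat_south_rule_lat, 14.0, np.nan), dt)
    init = np.minimum(init, scenario.peat_zero_age_ka)
    init = apply_peat_initiation_rule(
        init, lat2, scenario.peat_south_rule_lat, scenario.peat_south_rule_init_ka
    )

    truth = masks.copy()
    truth["biome_true"] = biome_true
    truth["elev"] = (("lat", "lon"), elev)
    truth["slope_frac"] = (("lat", "lon"), slope_frac)
    truth["loess_id"] = (("lat", "lon"), loess_id)
    truth["peat_pi_frac"] = (("lat", "lon"), pi_frac)
    truth["peat_init"] = (("lat", "lon"), init)

    return World(
        domain=domain,
        scenario=scenario,
        seed=seed,
        climates=climates,
        truth=truth,
        loess_table=loess_table,
        peat_curves=peat_curves,
        deglac_time=dt,
    )
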