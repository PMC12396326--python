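"""End-to-end reconstruction pipeline.

Sequencing mirrors the reconstruction's method order: synthetic world ->
biome training and vote-fraction prediction per climate model -> permafrost
delineation -> per-millennium carbon ledger (both models averaged for
mineral stocks) -> net/gross changes -> atmospheric CO2 series.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atmosphere, biomes, ledger, permafrost, world as world_mod
from .atmosphere import AtmosphereConstants
from .ledger import CarbonState, FluxRecord, TransferFunctionTable
from .permafrost import MaatAdjustment, PermafrostParams
from .world import MODELS, Scenario, TIMES_KA, World, build_world

log = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    n_estimators: int = 500
    max_depth: int | None = None
    holdout_fraction: float = 0.25


@dataclass
class LedgerConfig:
    cycling_fraction: float = 0.30
    retention_on_thaw: float = 0.10
    # "anchors" (default): total loess stock interpolated between the
    # isochrone anchor chronology; "permafrost": driven by the modeled
    # continuous-permafrost masks (sensitivity mode)
    loess_mode: str = "anchors"
    loess_anchors: dict = field(default_factory=lambda: dict(ledger.DEFAULT_LOESS_ANCHORS))
    allow_readvance: bool = False


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: scenario + stage parameters + seed."""

    seed: int = 0
    resolution: float = 1.0
    scenario: Scenario = field(default_factory=Scenario)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    permafrost_params: PermafrostParams = field(default_factory=PermafrostParams)
    maat_adjustment: MaatAdjustment = field(default_factory=MaatAdjustment)
    transfer_functions: TransferFunctionTable = field(default_factory=TransferFunctionTable)
    constants: AtmosphereConstants = field(default_factory=AtmosphereConstants)
    ledger: LedgerConfig = field(default_factory=LedgerConfig)

    def quick(self) -> "RunConfig":
        """CI-scale copy: smaller ensemble and training set, same science."""
        cfg = dataclasses.replace(self)
        cfg.classifier = dataclasses.replace(self.classifier, n_estimators=60)
        cfg.scenario = dataclasses.replace(self.scenario, n_per_slice=120)
        return cfg

    def to_dict(self) -> dict:
        return _as_plain(dataclasses.asdict(self))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as e:
            raise world_mod.ConfigurationError(f"unreadable config: {e}") from e
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        for section, target in (
            ("scenario", cfg.scenario),
            ("classifier", cfg.classifier),
            ("permafrost_params", cfg.permafrost_params),
            ("maat_adjustment", cfg.maat_adjustment),
            ("constants", cfg.constants),
            ("ledger", cfg.ledger),
        ):
            for k, v in (raw.get(section) or {}).items():
                if not hasattr(target, k):
                    raise world_mod.ConfigurationError(
                        f"unknown config field {section}.{k}"
                    )
                if k == "biome_rules":
                    v = world_mod.BiomeRules(**v)
                if k == "loess_regions":
                    v = [world_mod.LoessRegionSpec(**r) for r in v]
                object.__setattr__(target, k, v) if dataclasses.is_dataclass(target) and getattr(
                    type(target), "__dataclass_params__"
                ).frozen else setattr(target, k, v)
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.resolution = float(raw.get("resolution", cfg.resolution))
        return cfg


def _as_plain(obj):
    if isinstance(obj, dict):
        return {
            ("|".join(map(str, k)) if isinstance(k, tuple) else k): _as_plain(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def validate_config(config: RunConfig) -> list[str]:
    """Static precondition check; returns one message per violation."""
    v: list[str] = []
    lc = config.ledger
    if not (0 <= lc.cycling_fraction <= 0.66):
        v.append(
            f"ledger.cycling_fraction={lc.cycling_fraction} outside the supported "
            "0-0.66 range"
        )
    if not (0 <= lc.retention_on_thaw <= 1):
        v.append("ledger.retention_on_thaw must be in [0, 1]")
    if lc.loess_mode not in ("permafrost", "anchors"):
        v.append(f"ledger.loess_mode={lc.loess_mode!r} not one of permafrost|anchors")
    if config.classifier.n_estimators <= 0:
        v.append("classifier.n_estimators must be positive")
    if not (0 < config.classifier.holdout_fraction < 1):
        v.append("classifier.holdout_fraction must be in (0, 1)")
    if config.permafrost_params.s_c <= 0:
        v.append("permafrost_params.s_c must be positive")
    if not (0 < config.permafrost_params.continuous_threshold <= 1):
        v.append("permafrost_params.continuous_threshold must be in (0, 1]")
    sc = config.scenario
    if not (0 <= sc.label_noise <= 1):
        v.append("scenario.label_noise must be in [0, 1]")
    if sc.n_per_slice < 1:
        v.append("scenario.n_per_slice must be >= 1")
    if not (0 <= sc.loess_retention_on_thaw <= 1):
        v.append("scenario.loess_retention_on_thaw must be in [0, 1]")
    try:
        sc.biome_rules.validate()
    except world_mod.ConfigurationError as e:
        v.append(str(e))
    try:
        from .grid import make_domain

        make_domain(config.resolution)
    except Exception as e:
        v.append(str(e))
    return v


@dataclass
class RunReport:
    """All tables a run produces, regenerable bit-identically from config."""

    pools: pd.DataFrame          # time_ka, pool, mean_PgC, sd_PgC
    fluxes: pd.DataFrame         # interval, pool deltas, cycled, net, E
    ppm: pd.DataFrame
    accuracy: pd.DataFrame       # per period/slice holdout accuracy
    permafrost_extent: pd.DataFrame
    gross: pd.DataFrame
    provenance: dict
    states: list = field(default_factory=list)
    flux_records: list = field(default_factory=list)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pools.to_csv(outdir / "pools.csv", index=False)
        self.fluxes.to_csv(outdir / "fluxes.csv", index=False)
        self.ppm.to_csv(outdir / "ppm.csv", index=False)
        self.accuracy.to_csv(outdir / "accuracy.csv", index=False)
        self.permafrost_extent.to_csv(outdir / "permafrost_extent.csv", index=False)
        self.gross.to_csv(outdir / "gross_changes.csv", index=False)
        (outdir / "provenance.json").write_text(json.dumps(self.provenance, indent=2))


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_reconstruction(config: RunConfig, world: World | None = None) -> RunReport:
    """Execute every stage and assemble the run report."""
    violations = validate_config(config)
    if violations:
        raise world_mod.ConfigurationError("; ".join(violations))
    t0 = _time.time()
    rng = np.random.default_rng(config.seed)
    sub = rng.integers(0, 2**31 - 1, size=4)

    if world is None:
        world = build_world(config.scenario, seed=int(sub[0]), resolution=config.resolution)
    dom = world.domain
    log.info("world built in %.1fs", _time.time() - t0)

    # --- training, classifiers, accuracy -----------------------------------
    train = world_mod.sample_pollen_sites(
        world,
        config.scenario.n_per_slice,
        config.scenario.label_noise,
        config.scenario.protected_rate,
        seed=int(sub[1]),
    )
    train = biomes.filter_training(train)
    split_rng = np.random.default_rng(int(sub[2]))
    holdout_mask = split_rng.random(len(train)) < config.classifier.holdout_fraction
    holdout = train[holdout_mask].reset_index(drop=True)
    fit_rows = train[~holdout_mask].reset_index(drop=True)
    per_period = biomes.augment_deserts(fit_rows, world, seed=int(sub[3]))
    bundles, acc_frames = {}, []
    for period, rows in per_period.items():
        bundles[period] = biomes.fit_biome_classifier(
            rows,
            period,
            seed=int(sub[3]),
            n_estimators=config.classifier.n_estimators,
            max_depth=config.classifier.max_depth,
        )
        acc = biomes.evaluate_accuracy(bundles[period], holdout)
        acc["period"] = period
        acc_frames.append(acc)
    accuracy = pd.concat(acc_frames, ignore_index=True)

    # --- per-model, per-millennium fields ----------------------------------
    elev = world.truth["elev"].values
    slope = world.truth["slope_frac"].values
    loess_id = world.truth["loess_id"].values
    region_names = list(world.loess_table["name"]) if len(world.loess_table) else []

    pf_masks: dict[str, dict[int, np.ndarray]] = {m: {} for m in MODELS}
    fractions: dict[str, dict[int, np.ndarray]] = {m: {} for m in MODELS}
    pf_extent_rows = []
    for model in MODELS:
        clim = world.climates[model]
        for t in TIMES_KA:
            land = world.land(t)
            maat = clim["maat"].sel(time=t).values
            adj = permafrost.adjust_maat(maat, model, t, config.maat_adjustment)
            frac = permafrost.permafrost_fraction(adj, config.permafrost_params)
            mask, area_km2 = permafrost.delineate_continuous(
                np.where(land, frac, 0.0),
                dom.cell_area,
                config.permafrost_params.continuous_threshold,
            )
            pf_masks[model][t] = mask
            pf_extent_rows.append(
                {"time_ka": t, "model": model, "area_km2": area_km2}
            )
            bundle = bundles[biomes.period_for_time(t)]
            fractions[model][t] = biomes.predict_biome_fractions(
                bundle, clim.sel(time=t), land, elev
            )
    permafrost_extent = pd.DataFrame(pf_extent_rows)

    # --- ledger -------------------------------------------------------------
    def region_frozen_frac(t: int) -> dict[str, float]:
        out = {}
        for i, name in enumerate(region_names):
            cells = loess_id == i
            n = int(cells.sum())
            if n == 0:
                out[name] = 0.0
                continue
            fracs = [float((pf_masks[m][t] & cells).sum()) / n for m in MODELS]
            out[name] = float(np.mean(fracs))
        return out

    lt = world.loess_table
    loess_state = {
        row["name"]: {"frozen": float(row["stock_frozen_pgc"]), "thawed": 0.0}
        for _, row in lt.iterrows()
    }
    depo_total = config.scenario.loess_deposition_pgc_per_ka
    depo_shares = (
        {
            row["name"]: float(row["stock_frozen_pgc"]) / max(lt["stock_frozen_pgc"].sum(), 1e-12)
            for _, row in lt.iterrows()
        }
        if len(lt)
        else {}
    )
    anchors_traj = ledger.loess_anchor_trajectory(config.ledger.loess_anchors, TIMES_KA)

    states: list[CarbonState] = []
    cycled: dict[int, float] = {}
    inundated_pool = 0.0
    prev_map = None
    prev_frozen = region_frozen_frac(21)
    land_pi = world.land(0)

    for i, t in enumerate(TIMES_KA):
        land = world.land(t)
        shelf = world.shelf(t)
        peat = ledger.peat_step(
            world.peat_curves,
            t,
            land,
            world.truth["peat_init"].values,
            world.truth["peat_pi_frac"].values,
            dom.cell_area,
        )
        age = world.deglac_time - t  # ka since deglaciation; NaN if never iced
        per_model = []
        for model in MODELS:
            frs = fractions[model][t]
            pf = pf_masks[model][t]
            acc_density = ledger.accrual_density_map(frs, config.transfer_functions, pf, age)
            per_model.append(
                ledger.mineral_stock(
                    frs,
                    config.transfer_functions,
                    pf,
                    peat["frac"],
                    slope,
                    dom.cell_area,
                    land,
                    shelf,
                    accrual_age=age,
                    accrual_density=acc_density,
                )
            )
        mineral = ledger.average_models(per_model[0], per_model[1])

        # loess
        if config.ledger.loess_mode == "anchors":
            total_loess = float(anchors_traj[i]) if len(lt) else 0.0
            rel_sd = (
                float(
                    np.sqrt(
                        sum(
                            (ledger.loess_region_sd(r) * s) ** 2
                            for (_, r), s in zip(lt.iterrows(), depo_shares.values())
                        )
                    )
                )
                if len(lt)
                else 0.0
            )
            loess_pool = (total_loess, total_loess * rel_sd)
        else:
            if t < 21:
                new_frozen = region_frozen_frac(t)
                depo = (
                    {r: depo_total * s for r, s in depo_shares.items()}
                    if t >= config.scenario.loess_deposition_end_ka
                    else None
                )
                loess_state, _ = ledger.loess_step(
                    loess_state,
                    prev_frozen,
                    new_frozen,
                    deposition_pgc=depo,
                    retention_on_thaw=config.ledger.retention_on_thaw,
                )
                prev_frozen = new_frozen
            total_loess = sum(s["frozen"] + s["thawed"] for s in loess_state.values())
            var = 0.0
            for _, row in lt.iterrows():
                st = loess_state[row["name"]]
                var += (ledger.loess_region_sd(row) * (st["frozen"] + st["thawed"])) ** 2
            loess_pool = (total_loess, float(np.sqrt(var)))

        # subglacial
        cold_area = float(
            dom.cell_area[world.truth["cold_based"].sel(time=t).values].sum()
        )
        sub_pool = ledger.subglacial_stock(cold_area)

        # shelf transfer from the previous millennium's map
        if prev_map is not None:
            tr = ledger.shelf_transfer(
                world.land(t + 1),
                land,
                land_pi,
                prev_map,
                config.ledger.cycling_fraction,
                inundated_pool,
            )
            inundated_pool = tr["inundated_pool_pgc"]
            cycled[t] = tr["cycled_flux_pgc"]

        pools = {
            "mineral_land": mineral["mineral_land"],
            "mineral_exposed_shelf": mineral["mineral_exposed_shelf"],
            "mineral_inundated": (inundated_pool, 0.36 * inundated_pool),
            "peat": peat["peat"],
            "loess_deep": loess_pool,
            "subglacial": sub_pool,
            "postglacial_accruing": mineral["postglacial_accruing"],
        }
        state = CarbonState(
            time=t, pools=pools, mineral_map=mineral["map"], peat_map=peat["map"]
        )
        states.append(state)
        prev_map = mineral["map"]

    # --- fluxes, gross changes, ppm -----------------------------------------
    flux_records: list[FluxRecord] = []
    gross_rows = []
    for old, young in zip(states[:-1], states[1:]):
        fr = ledger.net_change(old, young, cycled.get(young.time, 0.0))
        flux_records.append(fr)
        gains, losses = ledger.gross_changes(old.total_map(), young.total_map())
        gross_rows.append(
            {
                "t_old_ka": old.time,
                "t_young_ka": young.time,
                "gross_gain_pgc": gains,
                "gross_loss_pgc": losses,
            }
        )
    ppm = atmosphere.ppm_series(flux_records, config.constants)

    pools_rows = [
        {"time_ka": s.time, "pool": p, "mean_PgC": m, "sd_PgC": sd}
        for s in states
        for p, (m, sd) in s.pools.items()
    ]
    flux_rows = [
        {
            "t_old_ka": fr.t_old,
            "t_young_ka": fr.t_young,
            **{f"delta_{p}_PgC": d for p, d in fr.pool_deltas.items()},
            "cycled_PgC": fr.cycled_flux_pgc,
            "net_PgC": fr.net_to_atmosphere_pgc,
            "E_PgC": fr.net_uncertainty_pgc,
        }
        for fr in flux_records
    ]
    report = RunReport(
        pools=pd.DataFrame(pools_rows),
        fluxes=pd.DataFrame(flux_rows),
        ppm=ppm,
        accuracy=accuracy,
        permafrost_extent=permafrost_extent,
        gross=pd.DataFrame(gross_rows),
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "elapsed_s": round(_time.time() - t0, 2),
            "classifier_warnings": {
                p: b.meta.get("warnings", []) for p, b in bundles.items()
            },
        },
        states=states,
        flux_records=flux_records,
    )
    log.info("run complete in %.1fs", _time.time() - t0)
    return report
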