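"""Vote-fraction biome classification.

A random-forest ensemble is trained on (climate, biome-label) points and
its per-class vote fractions are read as per-cell biome *area* fractions,
letting several biomes occupy one grid cell.  Training follows the study's
hygiene rules: the record is split into a climatically stable Holocene
period (9-0 ka) and a dynamic deglacial period (21-10 ka, deliberately
overlapping at 10-9 ka), implausible warm "tundra" labels are dropped
unless protected, and scarce desert evidence is augmented with synthetic
sites in known desert areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .world import BIOME_CLASSES, CLIMATE_VARS, REFERENCE_MODEL, World

log = logging.getLogger(__name__)

FEATURES = list(CLIMATE_VARS) + ["elev"]

HOLOCENE = "holocene"
DEGLACIAL = "deglacial"
PERIOD_SLICES = {
    HOLOCENE: tuple(range(9, -1, -1)),
    DEGLACIAL: tuple(range(21, 9, -1)),
}

TUNDRA_MAAT_LIMIT_C = 5.0


class MissingClimateError(ValueError):
    """A training row lacks a resolvable climate covariate."""


def period_for_time(t: int) -> str:
    """Boundary assignment: 10 ka scored by the deglacial model, 9 ka by
    the Holocene model."""
    if t < 0 or t > 21:
        raise ValueError(f"time {t} ka outside 0..21")
    return DEGLACIAL if t >= 10 else HOLOCENE


@dataclass
class ClassifierBundle:
    period: str
    model: RandomForestClassifier
    features: list[str]
    classes: tuple[str, ...]
    meta: dict = field(default_factory=dict)


def filter_training(train: pd.DataFrame) -> pd.DataFrame:
    """Drop unprotected tundra rows whose site MAAT exceeds 5 degC.

    Such labels are implausible for a cold biome and are treated as
    interpretation errors; protected rows (the curated-source exemption)
    are kept regardless.
    """
    if "maat" not in train.columns or train["maat"].isna().any():
        bad = train.index[train.get("maat", pd.Series(np.nan, index=train.index)).isna()]
        first = train.loc[bad[0]] if len(bad) else None
        raise MissingClimateError(
            "missing MAAT covariate"
            + (f" at site {first['site_id']} ({first['time_ka']} ka)" if first is not None else "")
        )
    drop = (
        (train["biome"] == "tundra")
        & (train["maat"] > TUNDRA_MAAT_LIMIT_C)
        & (~train["protected"].astype(bool))
    )
    return train.loc[~drop].reset_index(drop=True)


def _desert_rows(world: World, t: int, n: int, rng: np.random.Generator) -> pd.DataFrame:
    biome = world.truth["biome_true"].sel(time=t).values
    desert_code = BIOME_CLASSES.index("desert")
    cells = np.flatnonzero(biome.ravel() == desert_code)
    if cells.size < n:
        raise ValueError(
            f"desert augmentation needs {n} cells at {t} ka, only {cells.size} available"
        )
    picks = rng.choice(cells, size=n, replace=False)
    iy, ix = np.unravel_index(picks, biome.shape)
    clim = world.climates[REFERENCE_MODEL].sel(time=t)
    elev = world.truth["elev"].values
    return pd.DataFrame(
        {
            "site_id": -1,
            "lon": world.domain.lon[ix],
            "lat": world.domain.lat[iy],
            "time_ka": t,
            "biome": "desert",
            "protected": False,
            **{v: clim[v].values[iy, ix] for v in CLIMATE_VARS},
            "elev": elev[iy, ix],
        }
    )


def augment_deserts(
    train: pd.DataFrame,
    world: World,
    seed: int,
    n_holocene_pi: int = 242,
    n_deglacial_lgm: int = 40,
) -> dict[str, pd.DataFrame]:
    """Split training by period and add synthetic desert sites.

    The Holocene set gains ``n_holocene_pi`` desert rows at 0 ka; the
    deglacial set gains a copy of every 6-ka desert row plus
    ``n_deglacial_lgm`` random desert rows at 21 ka.  Defaults are the
    study's printed counts.
    """
    rng = np.random.default_rng(seed)
    holo = train[train["time_ka"].isin(PERIOD_SLICES[HOLOCENE])]
    degl = train[train["time_ka"].isin(PERIOD_SLICES[DEGLACIAL])]
    holo = pd.concat(
        [holo, _desert_rows(world, 0, n_holocene_pi, rng)], ignore_index=True
    )
    mid_holocene_desert = train[(train["time_ka"] == 6) & (train["biome"] == "desert")]
    degl = pd.concat(
        [degl, mid_holocene_desert, _desert_rows(world, 21, n_deglacial_lgm, rng)],
        ignore_index=True,
    )
    return {HOLOCENE: holo, DEGLACIAL: degl}


def fit_biome_classifier(
    train: pd.DataFrame,
    period: str,
    seed: int,
    n_estimators: int = 500,
    max_depth: int | None = None,
) -> ClassifierBundle:
    """Fit the vote-fraction ensemble for one period.

    The predicted class probability is literally the fraction of trees
    voting for that class, which downstream becomes the biome's areal
    fraction of a grid cell.
    """
    rows = train[train["time_ka"].isin(PERIOD_SLICES[period])]
    if rows.empty:
        raise ValueError(f"no training rows within the {period} period")
    meta: dict = {"n_rows": len(rows), "seed": seed, "warnings": []}
    present = set(rows["biome"])
    for c in BIOME_CLASSES:
        if c not in present:
            msg = f"class {c!r} absent from {period} training"
            meta["warnings"].append(msg)
            log.warning(msg)
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(rows[FEATURES].to_numpy(), rows["biome"].to_numpy())
    return ClassifierBundle(
        period=period, model=model, features=FEATURES, classes=BIOME_CLASSES, meta=meta
    )


def _proba_canonical(bundle: ClassifierBundle, X: np.ndarray) -> np.ndarray:
    """predict_proba reordered onto the fixed class list (absent classes 0)."""
    proba = bundle.model.predict_proba(X)
    out = np.zeros((X.shape[0], len(BIOME_CLASSES)))
    for j, c in enumerate(bundle.model.classes_):
        out[:, BIOME_CLASSES.index(c)] = proba[:, j]
    return out


def predict_biome_fractions(
    bundle: ClassifierBundle,
    climate_slice,
    land_mask: np.ndarray,
    elev: np.ndarray,
) -> np.ndarray:
    """Per-cell biome area fractions, shape (8, nlat, nlon).

    Fractions on land cells are the ensemble vote fractions (summing to 1);
    ice and ocean cells get the zero vector.
    """
    t = int(climate_slice["time"])
    if period_for_time(t) != bundle.period:
        raise ValueError(f"slice {t} ka is outside the {bundle.period} model's period")
    ny, nx = land_mask.shape
    out = np.zeros((len(BIOME_CLASSES), ny, nx))
    iy, ix = np.nonzero(land_mask)
    if iy.size == 0:
        return out
    cols = [climate_slice[v].values[iy, ix] for v in CLIMATE_VARS] + [elev[iy, ix]]
    X = np.column_stack(cols)
    proba = _proba_canonical(bundle, X)
    out[:, iy, ix] = proba.T
    return out


def evaluate_accuracy(bundle: ClassifierBundle, holdout: pd.DataFrame) -> pd.DataFrame:
    """Per-slice argmax accuracy on held-out rows.

    Empty slices within the bundle's period are omitted with a warning.
    Ties in the vote fractions break toward the lower canonical class index.
    """
    recs = []
    for t in PERIOD_SLICES[bundle.period]:
        rows = holdout[holdout["time_ka"] == t]
        if rows.empty:
            log.warning("holdout slice %s ka empty; omitted", t)
            continue
        proba = _proba_canonical(bundle, rows[FEATURES].to_numpy())
        pred = np.argmax(proba, axis=1)
        truth = rows["biome"].map({c: i for i, c in enumerate(BIOME_CLASSES)}).to_numpy()
        recs.append(
            {"time_ka": t, "n": len(rows), "accuracy": float((pred == truth).mean())}
        )
    return pd.DataFrame(recs)
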