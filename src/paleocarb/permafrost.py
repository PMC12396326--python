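"""Permafrost extent from mean annual air temperature.

Per-cell permafrost fraction follows a two-parameter logistic in MAAT
(an empirical air-temperature/permafrost relationship); cells at the
saturation threshold are delineated as continuous permafrost, the only
permafrost class used downstream.  Because the logistic needs absolute
temperatures, each climate ensemble gets a bias adjustment: a constant
per-model offset (default +5 degC for the cold-biased ensemble) plus a
ramp that cools older slices by 1 degC per millennium between 10 and
17 ka, holding at -7 degC beyond, so the glacial extent matches the
well-constrained European evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .world import BIASED_MODEL, REFERENCE_MODEL


@dataclass
class PermafrostParams:
    t0_c: float = -6.0  # MAAT of 50% permafrost probability
    s_c: float = 1.5    # logistic width
    continuous_threshold: float = 0.99  # numerical stand-in for "100% coverage"


@dataclass
class MaatAdjustment:
    """Piecewise-linear, continuous-in-time MAAT correction per model."""

    base_offset_c: dict = field(
        default_factory=lambda: {REFERENCE_MODEL: 0.0, BIASED_MODEL: 5.0}
    )
    ramp_c_per_ka: float = -1.0
    ramp_start_ka: float = 10.0
    ramp_end_ka: float = 17.0
    # "from_start": 0 at ramp_start growing with t; "at_start": already one
    # ramp increment at ramp_start (alternative anchoring)
    anchoring: str = "from_start"

    def ramp_term(self, time_ka: float) -> float:
        span = self.ramp_end_ka - self.ramp_start_ka
        if self.anchoring == "from_start":
            steps = np.clip(time_ka - self.ramp_start_ka, 0.0, span)
        elif self.anchoring == "at_start":
            steps = np.clip(time_ka - self.ramp_start_ka + 1.0, 0.0, span + 1.0)
            steps = np.where(time_ka < self.ramp_start_ka, 0.0, steps)
        else:
            raise ValueError(f"unknown ramp anchoring {self.anchoring!r}")
        return float(self.ramp_c_per_ka * steps)


def permafrost_fraction(maat_adjusted, params: PermafrostParams | None = None) -> np.ndarray:
    """Logistic permafrost fraction 1/(1+exp((T-T0)/s)).

    Strictly decreasing in T; saturates to 1 (0) for very cold (warm) MAAT.
    """
    params = params or PermafrostParams()
    if params.s_c <= 0:
        raise ValueError("logistic width s must be positive")
    T = np.asarray(maat_adjusted, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("non-finite temperature in permafrost computation")
    return expit(-(T - params.t0_c) / params.s_c)


def adjust_maat(maat, model_label: str, time_ka: float, adj: MaatAdjustment | None = None):
    """Apply the per-model offset and the deglacial ramp to MAAT."""
    adj = adj or MaatAdjustment()
    if not (0 <= time_ka <= 21):
        raise ValueError(f"time {time_ka} ka outside 0..21")
    if model_label not in adj.base_offset_c:
        raise ValueError(f"unknown model label {model_label!r}")
    return np.asarray(maat, dtype=float) + adj.base_offset_c[model_label] + adj.ramp_term(time_ka)


def delineate_continuous(
    fraction: np.ndarray,
    cell_area: np.ndarray | None = None,
    threshold: float = 0.99,
) -> tuple[np.ndarray, float]:
    """Continuous-permafrost mask (fraction >= threshold) and its area.

    Returns (mask, area_km2); area is 0 if no cell areas are supplied.
    """
    if not (0 < threshold <= 1):
        raise ValueError("continuous threshold must be in (0, 1]")
    mask = np.asarray(fraction) >= threshold
    area_km2 = float((cell_area[mask]).sum() / 1e6) if cell_area is not None else 0.0
    return mask, area_km2


def symmetric_difference_area(
    mask_a: np.ndarray, mask_b: np.ndarray, cell_area: np.ndarray
) -> float:
    """Area (km^2) where two delineations disagree; 0 iff the masks match."""
    return float(cell_area[np.logical_xor(mask_a, mask_b)].sum() / 1e6)


def calibrate_offsets(
    maat_by_time: dict[float, np.ndarray],
    reference_masks: dict[float, np.ndarray],
    cell_area: np.ndarray,
    model_label: str,
    params: PermafrostParams | None = None,
    adj: MaatAdjustment | None = None,
    search_range_c: tuple[float, float] = (-10.0, 10.0),
    step_c: float = 0.5,
    score_mask: np.ndarray | None = None,
) -> tuple[MaatAdjustment, dict]:
    """Grid-search the model's base offset against reference extents.

    The offset (0.5 degC steps) minimises the symmetric-difference area
    against the present-day (0 ka) reference delineation; the ramp is never
    tuned.  Residual misfits at the other reference epochs (e.g. 6 and
    21 ka) are reported as diagnostics.  ``score_mask`` restricts scoring to
    a sub-domain (e.g. Europe, where the glacial evidence is conclusive).
    """
    params = params or PermafrostParams()
    base = adj or MaatAdjustment()
    if 0.0 not in reference_masks:
        raise ValueError("calibration requires a 0 ka reference mask")
    for t, m in reference_masks.items():
        if not np.any(m):
            raise ValueError(f"empty reference mask at {t} ka")
    area = cell_area if score_mask is None else np.where(score_mask, cell_area, 0.0)

    def misfit(offset: float, t: float) -> float:
        trial = dict(base.base_offset_c)
        trial[model_label] = offset
        a = MaatAdjustment(
            base_offset_c=trial,
            ramp_c_per_ka=base.ramp_c_per_ka,
            ramp_start_ka=base.ramp_start_ka,
            ramp_end_ka=base.ramp_end_ka,
            anchoring=base.anchoring,
        )
        frac = permafrost_fraction(adjust_maat(maat_by_time[t], model_label, t, a), params)
        mask, _ = delineate_continuous(frac, threshold=params.continuous_threshold)
        return symmetric_difference_area(mask, reference_masks[t], area)

    offsets = np.arange(search_range_c[0], search_range_c[1] + step_c / 2, step_c)
    scores = [misfit(o, 0.0) for o in offsets]
    best = float(offsets[int(np.argmin(scores))])
    fitted = dict(base.base_offset_c)
    fitted[model_label] = best
    result = MaatAdjustment(
        base_offset_c=fitted,
        ramp_c_per_ka=base.ramp_c_per_ka,
        ramp_start_ka=base.ramp_start_ka,
        ramp_end_ka=base.ramp_end_ka,
        anchoring=base.anchoring,
    )
    diagnostics = {
        "misfit_0ka_km2": float(np.min(scores)),
        **{
            f"residual_{int(t)}ka_km2": misfit(best, t)
            for t in reference_masks
            if t != 0.0 and t in maat_by_time
        },
    }
    return result, diagnostics
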