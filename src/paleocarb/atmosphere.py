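"""Uncertainty propagation and the Pg C <-> ppm CO2 translation.

The stock-change uncertainty follows the reconstruction's two printed
relations: V = sigma^2 / mu (as printed -- note this is *not* the standard
coefficient of variation sigma/mu) and E_delta = mean(V_t, V_t+1) * |delta|,
with independent components combined as the square root of summed
variances.  Net land-carbon transfers translate to atmospheric CO2 with a
constant 5.15e21 g atmosphere, a 25% airborne fraction for releases and a
~13% linear response for peat-driven uptake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AtmosphereConstants:
    atmosphere_mass_g: float = 5.15e21
    airborne_fraction: float = 0.25
    uptake_response: float = 0.13
    molar_mass_air_g_mol: float = 28.966
    molar_mass_c_g_mol: float = 12.011

    def __post_init__(self):
        if not (0 < self.airborne_fraction <= 1):
            raise ValueError("airborne fraction must be in (0, 1]")
        if not (0 < self.uptake_response <= 1):
            raise ValueError("uptake response must be in (0, 1]")

    @property
    def pgc_per_ppm(self) -> float:
        """Carbon mass (Pg) per ppm of atmospheric CO2, ~2.13."""
        mol_air = self.atmosphere_mass_g / self.molar_mass_air_g_mol
        return mol_air * 1e-6 * self.molar_mass_c_g_mol / 1e15


def cov(variance_pgc2: float, mean_pgc: float) -> float:
    """Stock-size-scaled variation V = sigma^2 / mu (dimensionally Pg C)."""
    if mean_pgc <= 0:
        raise ValueError("mean stock must be positive for V")
    return variance_pgc2 / mean_pgc


def change_uncertainty(v_t: float, v_t1: float, delta_pgc: float) -> float:
    """E_delta = mean(V_t, V_t+1) * |delta|; zero change has zero error."""
    if v_t < 0 or v_t1 < 0:
        raise ValueError("V terms must be non-negative")
    return 0.5 * (v_t + v_t1) * abs(delta_pgc)


def combine_errors(components) -> float:
    """Square root of summed variances over independent error components."""
    comps = np.asarray(list(components), dtype=float)
    if np.any(comps < 0):
        raise ValueError("error components must be non-negative")
    return float(np.sqrt(np.sum(comps**2)))


def pgc_to_ppm(
    delta_c_pgc: float,
    response_fraction: float,
    constants: AtmosphereConstants | None = None,
) -> float:
    """Translate a carbon transfer (Pg C) into a ppm CO2 change.

    Sign is preserved: by convention, a positive ``delta_c_pgc`` is a
    release from land and yields a positive ppm contribution.
    """
    constants = constants or AtmosphereConstants()
    return delta_c_pgc * response_fraction / constants.pgc_per_ppm


def ppm_to_pgc(ppm: float, response_fraction: float = 1.0,
               constants: AtmosphereConstants | None = None) -> float:
    constants = constants or AtmosphereConstants()
    return ppm * constants.pgc_per_ppm / response_fraction


def icecore_millennial_delta(series: pd.DataFrame) -> pd.DataFrame:
    """Per-millennium CO2 change from an ice-core record.

    ``series`` has columns ``age_ka`` and ``co2_ppm``.  Within each 1-ka
    bin [m, m+1) the net sum of consecutive-point differences telescopes to
    youngest-minus-oldest; the change is reported in the forward-time sense.
    Bins with fewer than 2 points are reported as missing (NaN), never zero.
    """
    df = series.sort_values("age_ka").reset_index(drop=True)
    if df["age_ka"].isna().any():
        raise ValueError("ice-core ages must be finite")
    bins = np.floor(df["age_ka"]).astype(int)
    recs = []
    for m in range(int(bins.min()), int(bins.max()) + 1):
        pts = df[bins == m]
        if len(pts) < 2:
            recs.append({"millennium_ka": m, "delta_ppm": np.nan, "n_points": len(pts)})
        else:
            delta = float(pts["co2_ppm"].iloc[0] - pts["co2_ppm"].iloc[-1])
            recs.append({"millennium_ka": m, "delta_ppm": delta, "n_points": len(pts)})
    return pd.DataFrame(recs)


def ppm_series(
    flux_records,
    constants: AtmosphereConstants | None = None,
) -> pd.DataFrame:
    """Modeled per-millennium ppm contribution from net land-C transfers.

    Net releases use the airborne fraction, net uptakes the (smaller)
    uptake-response factor -- the asymmetric treatment of source versus
    peat-dominated sink intervals.  Error bars are the E_delta bounds
    mapped through the same response.  Losses from land appear as positive
    ppm contributions.
    """
    constants = constants or AtmosphereConstants()
    recs = []
    for fr in flux_records:
        net = fr.net_to_atmosphere_pgc  # negative = loss from land
        released = -net
        resp = constants.airborne_fraction if released >= 0 else constants.uptake_response
        ppm = pgc_to_ppm(released, resp, constants)
        e = fr.net_uncertainty_pgc
        bounds = sorted(
            pgc_to_ppm(
                r,
                constants.airborne_fraction if r >= 0 else constants.uptake_response,
                constants,
            )
            for r in (released - e, released + e)
        )
        recs.append(
            {
                "t_old_ka": fr.t_old,
                "t_young_ka": fr.t_young,
                "net_pgc": net,
                "e_pgc": e,
                "ppm": ppm,
                "ppm_lo": bounds[0],
                "ppm_hi": bounds[1],
            }
        )
    return pd.DataFrame(recs)


def cumulative_ppm(
    net_pgc_values,
    constants: AtmosphereConstants | None = None,
) -> float:
    """ppm contribution of a cumulative net transfer over a span.

    The response factor is applied to the cumulative sum (the mode used for
    the headline deglacial and Holocene figures): the airborne fraction if
    the span is a net release, the uptake response if a net gain.
    """
    constants = constants or AtmosphereConstants()
    total = float(np.sum(net_pgc_values))
    released = -total
    resp = constants.airborne_fraction if released >= 0 else constants.uptake_response
    return pgc_to_ppm(released, resp, constants)
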