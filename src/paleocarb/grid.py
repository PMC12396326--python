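"""Polar-cap grid (23-90 degrees N) with spherical cell areas.

The reconstruction domain is the land surface north of 23 degrees N on a
regular latitude-longitude grid (1 degree by default).  Cell areas follow
the spherical band formula, so the sum over the cap equals the analytic
cap area 2*pi*R^2*(1 - sin 23) to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_371_000.0
LAT_SOUTH = 23.0
LAT_NORTH = 90.0


class InvalidParameterError(ValueError):
    """A structural parameter (resolution, threshold, ...) is out of range."""


@dataclass(frozen=True)
class GridDomain:
    """Regular lat/lon grid over the northern cap.

    Cell centers sit at half-resolution offsets; latitude edges are
    inclusive-lower / exclusive-upper.  ``cell_area`` is in m^2 and varies
    with latitude only.
    """

    resolution: float
    lat: np.ndarray
    lon: np.ndarray
    lat_edges: np.ndarray
    lon_edges: np.ndarray
    cell_area: np.ndarray  # (nlat, nlon), m^2

    @property
    def nlat(self) -> int:
        return self.lat.size

    @property
    def nlon(self) -> int:
        return self.lon.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def total_area(self) -> float:
        """Total cap area in m^2."""
        return float(self.cell_area.sum())

    def lat2d(self) -> np.ndarray:
        return np.broadcast_to(self.lat[:, None], self.shape)

    def lon2d(self) -> np.ndarray:
        return np.broadcast_to(self.lon[None, :], self.shape)


def cap_area(lat_south: float = LAT_SOUTH, radius: float = EARTH_RADIUS_M) -> float:
    """Analytic area of the spherical cap north of ``lat_south``, m^2."""
    return 2.0 * np.pi * radius**2 * (1.0 - np.sin(np.deg2rad(lat_south)))


def make_domain(resolution: float = 1.0) -> GridDomain:
    """Build the northern-cap grid at the given resolution (degrees).

    The resolution must tile the 23-90 band and the 360-degree longitude
    circle evenly.
    """
    if not np.isfinite(resolution) or resolution <= 0:
        raise InvalidParameterError(f"resolution must be positive, got {resolution!r}")
    band = LAT_NORTH - LAT_SOUTH
    nlat = band / resolution
    nlon = 360.0 / resolution
    if abs(nlat - round(nlat)) > 1e-9 or abs(nlon - round(nlon)) > 1e-9:
        raise InvalidParameterError(
            f"resolution {resolution} does not tile the 23-90N band and the "
            "longitude circle evenly"
        )
    nlat, nlon = int(round(nlat)), int(round(nlon))
    lat_edges = LAT_SOUTH + resolution * np.arange(nlat + 1)
    lon_edges = -180.0 + resolution * np.arange(nlon + 1)
    lat = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    lon = 0.5 * (lon_edges[:-1] + lon_edges[1:])
    dlon = np.deg2rad(resolution)
    band_area = (
        EARTH_RADIUS_M**2
        * dlon
        * (np.sin(np.deg2rad(lat_edges[1:])) - np.sin(np.deg2rad(lat_edges[:-1])))
    )
    cell_area = np.repeat(band_area[:, None], nlon, axis=1)
    return GridDomain(
        resolution=resolution,
        lat=lat,
        lon=lon,
        lat_edges=lat_edges,
        lon_edges=lon_edges,
        cell_area=cell_area,
    )
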