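"""Rectilinear WGS84 lon/lat grids and great-circle geometry.

All rasters in the package live on a north-up rectilinear grid of cell
centres. Distances between points are haversine great-circle distances in
kilometres; nearest-neighbour searches use chord distance on the unit
sphere (monotone in haversine) through a KD-tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Inputs broadcast like numpy arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _unit_sphere(lon, lat):
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )


def km_to_chord(d_km: float) -> float:
    """Convert a haversine distance to the equivalent 3-D chord length."""
    return 2.0 * np.sin(min(d_km / EARTH_RADIUS_KM, np.pi) / 2.0)


class SphereIndex:
    """KD-tree over points on the sphere, queried by haversine radius."""

    def __init__(self, lon, lat):
        self.lon = np.asarray(lon, dtype=float)
        self.lat = np.asarray(lat, dtype=float)
        self._tree = cKDTree(_unit_sphere(self.lon, self.lat))

    def query(self, lon, lat, k=1, max_km=None):
        """Indices and haversine distances (km) of the k nearest points."""
        xyz = _unit_sphere(np.atleast_1d(lon), np.atleast_1d(lat))
        bound = np.inf if max_km is None else km_to_chord(max_km)
        dist, idx = self._tree.query(xyz, k=k, distance_upper_bound=bound)
        if k == 1:
            dist = dist.reshape(-1, 1)
            idx = idx.reshape(-1, 1)
        # chord -> great circle
        with np.errstate(invalid="ignore"):
            km = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(dist / 2.0, 0.0, 1.0))
        km[~np.isfinite(dist)] = np.inf
        return idx, km


@dataclass(frozen=True)
class Grid:
    """North-up rectilinear grid of cell centres.

    ``lon[j] = lon0 + j * dlon`` (west to east), ``lat[i] = lat0 - i * dlat``
    (row 0 is the northernmost). ``dlon`` and ``dlat`` are positive cell
    sizes in degrees.
    """

    lon0: float
    lat0: float
    dlon: float
    dlat: float
    nrows: int
    ncols: int

    def __post_init__(self):
        if self.dlon <= 0 or self.dlat <= 0:
            raise ValueError("cell sizes must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def lons(self) -> np.ndarray:
        return self.lon0 + np.arange(self.ncols) * self.dlon

    def lats(self) -> np.ndarray:
        return self.lat0 - np.arange(self.nrows) * self.dlat

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.lons(), self.lats())

    def cell_of(self, lon, lat):
        """Row/col of the cell whose centre is nearest (in degrees) to a point.

        Returns integer arrays; points outside the grid footprint (beyond
        half a cell from the outermost centres) map to -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.rint((lon - self.lon0) / self.dlon).astype(int)
        row = np.rint((self.lat0 - lat) / self.dlat).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def extent(self):
        """(lon_min, lon_max, lat_min, lat_max) of the cell-centre envelope."""
        lons, lats = self.lons(), self.lats()
        return lons[0], lons[-1], lats[-1], lats[0]

    def overlaps(self, other: "Grid") -> bool:
        a = self.extent()
        b = other.extent()
        return not (a[1] < b[0] or b[1] < a[0] or a[3] < b[2] or b[3] < a[2])
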