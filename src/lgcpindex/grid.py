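"""Regular latitude/longitude grids and great-circle geometry.

The survey domain is tiled by rectangular cells (default 0.3° latitude by
0.6° longitude).  Samples are assigned to the cell containing their tow
midpoint; all spatial correlation is computed between cell centroids using
great-circle (haversine) distance in kilometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable arrays.  Symmetric, non-negative, and
    zero only for coincident points (on the sphere of radius 6371 km).
    """
    lat1, lon1, lat2, lon2 = (np.deg2rad(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards against rounding for antipodal/coincident points
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid tiling the study domain.

    Cells are half-open boxes ``[edge, edge + d)`` starting from the
    lower-left origin ``(lat0, lon0)``, so every in-domain point belongs to
    exactly one cell.  Cell ids run row-major: ``cell = ilat * nlon + ilon``.
    """

    lat0: float = 51.0
    lon0: float = -3.5
    dlat: float = 0.3
    dlon: float = 0.6
    nlat: int = 33
    nlon: int = 22

    @property
    def n_cells(self) -> int:
        return self.nlat * self.nlon

    @property
    def lat_max(self) -> float:
        return self.lat0 + self.nlat * self.dlat

    @property
    def lon_max(self) -> float:
        return self.lon0 + self.nlon * self.dlon

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) arrays of length ``n_cells``, row-major cell order."""
        lat_c = self.lat0 + (np.arange(self.nlat) + 0.5) * self.dlat
        lon_c = self.lon0 + (np.arange(self.nlon) + 0.5) * self.dlon
        glat, glon = np.meshgrid(lat_c, lon_c, indexing="ij")
        return glat.ravel(), glon.ravel()

    def contains(self, lat, lon) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        return ((lat >= self.lat0) & (lat < self.lat_max)
                & (lon >= self.lon0) & (lon < self.lon_max))

    def cell_of(self, lat, lon) -> np.ndarray:
        """Cell id of each point; -1 for out-of-domain points.

        Points on a shared edge belong to the cell whose lower edge they lie
        on (half-open convention).
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        # tiny nudge so points on a representable shared edge fall in the cell
        # whose lower edge they lie on despite floating-point rounding
        ilat = np.floor((lat - self.lat0) / self.dlat + 1e-9).astype(int)
        ilon = np.floor((lon - self.lon0) / self.dlon + 1e-9).astype(int)
        cell = ilat * self.nlon + ilon
        return np.where(self.contains(lat, lon), cell, -1)

    def distance_matrix_km(self) -> np.ndarray:
        """Pairwise haversine distances between cell centroids (km)."""
        clat, clon = self.centroids()
        return haversine_km(clat[:, None], clon[:, None], clat[None, :], clon[None, :])

    def cell_areas_km2(self) -> np.ndarray:
        """Spherical cell areas in km², per cell (cos-latitude weighting)."""
        clat, _ = self.centroids()
        lat_lo = np.deg2rad(clat - self.dlat / 2.0)
        lat_hi = np.deg2rad(clat + self.dlat / 2.0)
        band = np.sin(lat_hi) - np.sin(lat_lo)
        return EARTH_RADIUS_KM ** 2 * np.deg2rad(self.dlon) * band
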