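"""Global latitude-longitude grids.

All spatial layers in the package (habitat masks, species ranges, diversity
maps) live on an equal-angle global grid.  Cells are numbered in row-major
order starting at the south-west corner (lon -180, lat -90); cell centroids
carry the geographic meaning, so a 1-degree grid has centroid latitudes
-89.5 ... 89.5 and centroid longitudes -179.5 ... 179.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LON_ORIGIN = -180.0
LAT_ORIGIN = -90.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a global equal-angle grid.

    Parameters
    ----------
    resolution_deg:
        Cell edge length in degrees.  Must divide both 360 and 180 exactly
        (e.g. 1 for simulation grids, 5 for empirical comparison grids).
    """

    resolution_deg: float = 1.0

    def __post_init__(self) -> None:
        res = float(self.resolution_deg)
        if res <= 0:
            raise ValueError("resolution_deg must be positive")
        if abs(360.0 / res - round(360.0 / res)) > 1e-9 or abs(
            180.0 / res - round(180.0 / res)
        ) > 1e-9:
            raise ValueError(
                f"resolution_deg={res} must divide 360 and 180 exactly"
            )

    @property
    def n_lon(self) -> int:
        return int(round(360.0 / self.resolution_deg))

    @property
    def n_lat(self) -> int:
        return int(round(180.0 / self.resolution_deg))

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    # -- id <-> (row, col) ---------------------------------------------------

    def rowcol(self, cell):
        """Row (south to north) and column (west to east) of ``cell``."""
        cell = np.asarray(cell)
        if np.any(cell < 0) or np.any(cell >= self.n_cells):
            raise ValueError("cell id out of range")
        return cell // self.n_lon, cell % self.n_lon

    def cell_id(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        if np.any(row < 0) or np.any(row >= self.n_lat):
            raise ValueError("row out of range")
        if np.any(col < 0) or np.any(col >= self.n_lon):
            raise ValueError("col out of range")
        return row * self.n_lon + col

    # -- geographic coordinates ---------------------------------------------

    def centroids(self, cells):
        """Centroid (lon, lat) arrays for an array of cell ids."""
        row, col = self.rowcol(np.asarray(cells))
        res = self.resolution_deg
        lon = LON_ORIGIN + (col + 0.5) * res
        lat = LAT_ORIGIN + (row + 0.5) * res
        return lon, lat

    def centroid(self, cell: int):
        lon, lat = self.centroids(np.asarray([cell]))
        return float(lon[0]), float(lat[0])

    def cell_at(self, lon: float, lat: float) -> int:
        """Cell id containing the point (lon, lat); lon wraps into [-180, 180)."""
        res = self.resolution_deg
        lon = (float(lon) - LON_ORIGIN) % 360.0 + LON_ORIGIN
        if not -90.0 <= lat <= 90.0:
            raise ValueError("latitude out of range")
        col = min(int((lon - LON_ORIGIN) / res), self.n_lon - 1)
        row = min(int((lat - LAT_ORIGIN) / res), self.n_lat - 1)
        return int(self.cell_id(row, col))

    def unit_vectors(self, cells) -> np.ndarray:
        """(n, 3) unit vectors of cell centroids on the sphere."""
        lon, lat = self.centroids(np.asarray(cells))
        lon_r = np.radians(lon)
        lat_r = np.radians(lat)
        cl = np.cos(lat_r)
        return np.column_stack((cl * np.cos(lon_r), cl * np.sin(lon_r), np.sin(lat_r)))
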