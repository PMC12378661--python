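"""Geographic bathymetry grid with plain-text (ESRI ASCII grid) I/O.

The grid is an axis-aligned WGS84 (EPSG:4326) raster of seafloor depth in
meters, positive down.  Cells with no data (land, or simply outside the
surveyed extent) carry NaN.  Row 0 is the northernmost row, matching the
ESRI ASCII grid layout, so the array reads like a map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class BathymetryGrid:
    """Seafloor depth raster on a regular geographic grid.

    Parameters
    ----------
    depth
        2-D float array, shape ``(nrows, ncols)``; meters positive down,
        NaN where there is no marine coverage.  Row 0 is the north edge.
    lat_min, lon_min
        Coordinates of the grid's south-west corner (degrees).
    cellsize
        Pixel edge length in degrees (square pixels).
    """

    depth: np.ndarray
    lat_min: float
    lon_min: float
    cellsize: float

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2:
            raise ValueError("depth must be a 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.depth.shape[0]

    @property
    def ncols(self) -> int:
        return self.depth.shape[1]

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.nrows * self.cellsize

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.ncols * self.cellsize

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Latitude (north→south) and longitude (west→east) of pixel centers."""
        lats = self.lat_max - (np.arange(self.nrows) + 0.5) * self.cellsize
        lons = self.lon_min + (np.arange(self.ncols) + 0.5) * self.cellsize
        return lats, lons

    def sample(self, lat, lon) -> np.ndarray:
        """Depth stored in the pixel containing each point.

        The lookup is the containing pixel only — no interpolation, no
        nearest-neighbour search.  Points on the raster's top/right edge
        fall into the adjacent edge pixel; points outside the raster
        extent, or over no-data pixels, return NaN.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        scalar = lat.ndim == 0
        lat, lon = np.atleast_1d(lat), np.atleast_1d(lon)
        finite = np.isfinite(lat) & np.isfinite(lon)
        lat_f = np.where(finite, lat, 0.0)
        lon_f = np.where(finite, lon, 0.0)
        row = np.floor((self.lat_max - lat_f) / self.cellsize).astype(int)
        col = np.floor((lon_f - self.lon_min) / self.cellsize).astype(int)
        # closed top/right boundary: a point exactly on lat_max / lon_max
        # belongs to the outermost pixel
        row[(lat == self.lat_max)] = 0
        col[(lon == self.lon_max)] = self.ncols - 1
        out = np.full(lat.shape, np.nan)
        ok = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        ok &= finite
        out[ok] = self.depth[row[ok], col[ok]]
        return out[0] if scalar else out

    def covers(self, lat, lon) -> np.ndarray:
        """True where the raster holds a finite depth for the point."""
        return np.isfinite(self.sample(lat, lon))

    # ------------------------------------------------------------------ I/O

    def write_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (plain text, georeferenced header)."""
        path = Path(path)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.lon_min!r}\n"
            f"yllcorner {self.lat_min!r}\n"
            f"cellsize {self.cellsize!r}\n"
            f"NODATA_value {NODATA}\n"
        )
        body = np.where(np.isfinite(self.depth), self.depth, NODATA)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.3f")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "BathymetryGrid":
        path = Path(path)
        meta: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            for _ in range(6):
                key, value = fh.readline().split()
                meta[key.lower()] = float(value)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = meta.get("nodata_value", NODATA)
        data = np.where(data == nodata, np.nan, data)
        return cls(
            depth=data,
            lat_min=meta["yllcorner"],
            lon_min=meta["xllcorner"],
            cellsize=meta["cellsize"],
        )
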