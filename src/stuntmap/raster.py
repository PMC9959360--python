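"""Minimal geo-referenced raster container with plain-text I/O.

A :class:`Raster` is a 2-D array plus a north-up affine geotransform in
EPSG:4326 (lon/lat degrees).  Persistence uses the ESRI ASCII grid
format (``.asc``), a plain-text interchange format readable by every
mainstream GIS.  Only square-ish, axis-aligned grids are supported —
exactly what the synthetic covariate surfaces and prediction grids need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NODATA_DEFAULT = -9999.0


@dataclass
class Raster:
    """North-up raster: row 0 is the northernmost row.

    Attributes
    ----------
    data : (nrows, ncols) float array
    lon_min, lat_min : lower-left corner of the grid extent (degrees)
    cellsize : pixel width = height (degrees)
    nodata : sentinel for missing pixels
    name, units : metadata carried through linkage and reporting
    """

    data: np.ndarray
    lon_min: float
    lat_min: float
    cellsize: float
    nodata: float = NODATA_DEFAULT
    name: str = ""
    units: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.lon_min,
            self.lat_min,
            self.lon_min + self.ncols * self.cellsize,
            self.lat_min + self.nrows * self.cellsize,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lons, lats) 1-D arrays of column / row center coordinates.

        lats follow array row order (north to south).
        """
        lons = self.lon_min + (np.arange(self.ncols) + 0.5) * self.cellsize
        lats = self.lat_min + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return lons, lats

    def index_of(self, lon, lat):
        """(row, col) arrays of the pixels containing the given points.

        Points outside the extent get index -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cellsize).astype(int)
        row_from_bottom = np.floor((lat - self.lat_min) / self.cellsize).astype(int)
        row = self.nrows - 1 - row_from_bottom
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def value_at(self, lon, lat):
        """Nearest-pixel value at each point; NaN outside extent or nodata."""
        row, col = self.index_of(lon, lat)
        scalar = np.ndim(row) == 0
        row, col = np.atleast_1d(row), np.atleast_1d(col)
        out = np.full(row.shape, np.nan)
        ok = row >= 0
        vals = self.data[row[ok], col[ok]]
        vals = np.where(vals == self.nodata, np.nan, vals)
        out[ok] = vals
        return float(out[0]) if scalar else out

    def masked(self) -> np.ndarray:
        """Data with nodata pixels replaced by NaN."""
        return np.where(self.data == self.nodata, np.nan, self.data)

    # ---- ESRI ASCII grid I/O -------------------------------------------

    def write_ascii(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {float(self.lon_min)!r}\n")
            fh.write(f"yllcorner {float(self.lat_min)!r}\n")
            fh.write(f"cellsize {float(self.cellsize)!r}\n")
            fh.write(f"NODATA_value {float(self.nodata)!r}\n")
            for row in self.data:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read_ascii(cls, path, name: str = "", units: str = "") -> "Raster":
        header: dict[str, float] = {}
        rows: list[np.ndarray] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                    header[key] = float(parts[1])
                else:
                    rows.append(np.array(parts, dtype=float))
        data = np.vstack(rows)
        if data.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError(f"grid shape {data.shape} disagrees with header")
        return cls(
            data=data,
            lon_min=header["xllcorner"],
            lat_min=header["yllcorner"],
            cellsize=header["cellsize"],
            nodata=header.get("nodata_value", NODATA_DEFAULT),
            name=name,
            units=units,
        )
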