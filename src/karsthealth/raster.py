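"""Lightweight raster container and plain-text raster / vector I/O.

Conventions used throughout the package:

* all geometry is in projected metres, in a single (unchecked beyond a tag)
  coordinate reference system;
* raster row 0 is the northernmost row; the geotransform is stored as the
  coordinates of the *top-left corner* of the top-left pixel plus a square
  pixel size;
* NoData is -9999.0 for continuous rasters and 0 for categorical ones.

Rasters are serialised as ESRI ASCII grids (a plain-text format every GIS
reads); point and polygon layers as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

FLOAT_NODATA = -9999.0
INT_NODATA = 0

#: land-use legend: integer code -> class name (code 0 reserved for NoData)
LANDUSE_LEGEND: dict[int, str] = {
    1: "farmland",
    2: "forestland",
    3: "shrubland",
    4: "high-density grassland",
    5: "mid-density grassland",
    6: "low-density grassland",
    7: "water",
    8: "unused",
    9: "built-up",
}

#: vegetated classes used for the vegetation-coverage proxy
VEGETATION_CLASSES = frozenset(
    {"forestland", "shrubland", "high-density grassland",
     "mid-density grassland", "low-density grassland"}
)

FOREST_CLASSES = frozenset({"forestland", "shrubland"})


@dataclass
class Raster:
    """A single-band raster on a square-pixel grid.

    Parameters
    ----------
    data:
        2-D array; integer dtype for categorical rasters, float for
        continuous ones.
    x_origin, y_origin:
        Projected coordinates (m) of the *top-left corner* of pixel (0, 0).
    cell_size:
        Pixel side length in metres.
    crs:
        Free-form CRS tag; operations combining rasters require equal tags.
    nodata:
        NoData marker stored in ``data``.
    legend:
        Optional code -> class-name map for categorical rasters.
    """

    data: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    crs: str = "local-metric"
    nodata: float = FLOAT_NODATA
    legend: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.legend is not None:
            codes = np.unique(self.data)
            unknown = [c for c in codes
                       if c != self.nodata and int(c) not in self.legend]
            if unknown:
                raise ValueError(f"codes {unknown} missing from legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the raster footprint."""
        n_rows, n_cols = self.data.shape
        return (
            self.x_origin,
            self.y_origin - n_rows * self.cell_size,
            self.x_origin + n_cols * self.cell_size,
            self.y_origin,
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of all pixel centers, row-major."""
        n_rows, n_cols = self.data.shape
        cols = np.arange(n_cols)
        rows = np.arange(n_rows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def valid_mask(self) -> np.ndarray:
        if np.issubdtype(self.data.dtype, np.floating):
            return (self.data != self.nodata) & np.isfinite(self.data)
        return self.data != self.nodata

    def same_registration(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.cell_size, other.cell_size)
            and self.crs == other.crs
        )

    def with_data(self, data: np.ndarray, **kw) -> "Raster":
        """New raster sharing this grid registration."""
        return replace(self, data=np.asarray(data), **kw)

    # ------------------------------------------------------------------ I/O

    def write_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (plus a sidecar legend for categories)."""
        path = Path(path)
        n_rows, n_cols = self.data.shape
        header = (
            f"ncols {n_cols}\n"
            f"nrows {n_rows}\n"
            f"xllcorner {self.x_origin!r}\n"
            f"yllcorner {self.y_origin - n_rows * self.cell_size!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        fmt = "%d" if np.issubdtype(self.data.dtype, np.integer) else "%.8g"
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data, fmt=fmt)
        if self.legend is not None:
            legend_path = path.with_suffix(path.suffix + ".legend.json")
            with open(legend_path, "w") as fh:
                json.dump({str(k): v for k, v in self.legend.items()}, fh,
                          indent=1)

    @classmethod
    def read_ascii(cls, path: str | Path, crs: str = "local-metric") -> "Raster":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        legend = None
        legend_path = path.with_suffix(path.suffix + ".legend.json")
        if legend_path.exists():
            with open(legend_path) as fh:
                legend = {int(k): v for k, v in json.load(fh).items()}
            data = data.astype(np.int64)
        n_rows = int(header["nrows"])
        cell = header["cellsize"]
        return cls(
            data=data,
            x_origin=header["xllcorner"],
            y_origin=header["yllcorner"] + n_rows * cell,
            cell_size=cell,
            crs=crs,
            nodata=header["nodata_value"],
            legend=legend,
        )


def write_points_geojson(points: np.ndarray, path: str | Path,
                         properties: list[dict] | None = None) -> None:
    """Write an (n, 2) array of point coordinates as a GeoJSON FeatureCollection."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    feats = []
    for i, (x, y) in enumerate(points):
        props = properties[i] if properties is not None else {"id": i}
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": props,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_points_geojson(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        gj = json.load(fh)
    return np.array(
        [f["geometry"]["coordinates"] for f in gj["features"]], dtype=float
    ).reshape(-1, 2)
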