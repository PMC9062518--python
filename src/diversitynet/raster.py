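"""Single-band raster grids with a geotransform, plus GeoTIFF/ASCII-grid IO.

A :class:`RasterLayer` is a rectangular grid of cell values anchored by its
top-left corner and a square cell size, in projected meters. Two on-disk
formats are supported:

* single-band TIFF with the GeoTIFF ``ModelPixelScale`` / ``ModelTiepoint``
  tags (read and written through :mod:`tifffile`);
* ESRI ASCII grid (``.asc``), a plain-text format convenient for fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_NODATA = 42113  # GDAL_NODATA


@dataclass
class RasterLayer:
    """One named raster layer on a regular grid.

    ``x_origin``/``y_origin`` locate the top-left *corner* of the grid; rows
    run north-to-south, so the center of cell (row, col) sits at
    ``(x_origin + (col + 0.5) * cell_size, y_origin - (row + 0.5) * cell_size)``.
    """

    name: str
    data: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("raster data must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        nrow, ncol = self.data.shape
        return (
            self.x_origin,
            self.y_origin - nrow * self.cell_size,
            self.x_origin + ncol * self.cell_size,
            self.y_origin,
        )

    def cell_index(self, x, y):
        """Row/column of the cell containing each point (nearest-cell lookup)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - y) / self.cell_size).astype(int)
        return row, col

    def value_at(self, x, y):
        """Nearest-cell values; nodata cells come back as NaN.

        Raises ``ValueError`` naming the first offending point if any point
        falls outside the grid footprint.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        row, col = self.cell_index(x, y)
        nrow, ncol = self.data.shape
        bad = (row < 0) | (row >= nrow) | (col < 0) | (col >= ncol)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"point ({x[i]:.1f}, {y[i]:.1f}) falls outside raster "
                f"'{self.name}' with bounds {self.bounds}"
            )
        values = self.data[row, col].astype(float)
        if self.nodata is not None:
            values = np.where(self.data[row, col] == self.nodata, np.nan, values)
        return values


def extract_raster_values(layers, x, y):
    """Nearest-cell value per layer per point.

    Parameters
    ----------
    layers : mapping of name -> RasterLayer, or iterable of RasterLayer
    x, y : array_like of projected coordinates

    Returns
    -------
    dict mapping layer name to an ndarray of values (NaN where nodata).
    """
    if hasattr(layers, "values") and not isinstance(layers, RasterLayer):
        layer_seq = list(layers.values())
    elif isinstance(layers, RasterLayer):
        layer_seq = [layers]
    else:
        layer_seq = list(layers)
    return {layer.name: layer.value_at(x, y) for layer in layer_seq}


def write_raster(layer: RasterLayer, path) -> Path:
    """Write a layer as GeoTIFF (.tif/.tiff) or ESRI ASCII grid (.asc)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_geotiff(layer, path)
    elif path.suffix.lower() == ".asc":
        _write_ascii_grid(layer, path)
    else:
        raise ValueError(f"unsupported raster extension: {path.suffix!r}")
    return path


def read_raster(path, name: str | None = None) -> RasterLayer:
    """Read a GeoTIFF or ESRI ASCII grid written by :func:`write_raster`."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _read_geotiff(path, name)
    if path.suffix.lower() == ".asc":
        return _read_ascii_grid(path, name)
    raise ValueError(f"unsupported raster extension: {path.suffix!r}")


def _write_geotiff(layer: RasterLayer, path: Path) -> None:
    import tifffile

    scale = (float(layer.cell_size), float(layer.cell_size), 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(layer.x_origin), float(layer.y_origin), 0.0)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, scale, True),
        (_TAG_TIEPOINT, "d", 6, tiepoint, True),
    ]
    if layer.nodata is not None:
        nd = str(layer.nodata)
        extratags.append((_TAG_NODATA, "s", len(nd) + 1, nd, True))
    tifffile.imwrite(
        path,
        layer.data.astype(np.float64),
        extratags=extratags,
        metadata=None,
        software=None,
    )


def _read_geotiff(path: Path, name: str | None) -> RasterLayer:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF geotransform tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tp = tags[_TAG_TIEPOINT].value
        x_origin = tp[3] - tp[0] * sx
        y_origin = tp[4] + tp[1] * sy
        nodata = None
        if _TAG_NODATA in tags:
            nodata = float(tags[_TAG_NODATA].value)
    if abs(sx - sy) > 1e-9 * max(sx, sy):
        raise ValueError(f"{path}: non-square cells are not supported")
    return RasterLayer(name or path.stem, data, x_origin, y_origin, float(sx), nodata)


def _write_ascii_grid(layer: RasterLayer, path: Path) -> None:
    nrow, ncol = layer.data.shape
    nodata = layer.nodata if layer.nodata is not None else -9999.0
    header = (
        f"ncols {ncol}\n"
        f"nrows {nrow}\n"
        f"xllcorner {layer.x_origin!r}\n"
        f"yllcorner {(layer.y_origin - nrow * layer.cell_size)!r}\n"
        f"cellsize {layer.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    data = np.where(np.isnan(layer.data), nodata, layer.data)
    with open(path, "w") as fh:
        fh.write(header)
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_ascii_grid(path: Path, name: str | None) -> RasterLayer:
    meta: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"} and len(parts) == 2:
                meta[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    data = np.array(rows, dtype=float)
    cell = meta["cellsize"]
    nodata = meta.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    y_origin = meta["yllcorner"] + data.shape[0] * cell
    return RasterLayer(name or path.stem, data, meta["xllcorner"], y_origin, cell,
                       nodata)
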