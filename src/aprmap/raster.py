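"""Raster container and GeoTIFF input/output.

A :class:`Raster` is a 2-D array plus an :class:`~aprmap.geo.Affine`
transform, a CRS identifier and a nodata sentinel. GeoTIFFs are written
through :mod:`tifffile` with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL_NODATA) so the files
open correctly in GDAL-based tooling; only axis-aligned (north-up) grids are
supported, which covers every product in this pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .geo import Affine, cell_area_ha

__all__ = ["Raster", "read_raster", "write_raster"]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoTIFF keys: model type (1 projected / 2 geographic), raster type,
# projected CS code, geographic CS code.
_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_CS = 2048
_KEY_PROJECTED_CS = 3072


@dataclass
class Raster:
    """Georeferenced 2-D grid (categorical codes or application rates)."""

    values: np.ndarray
    transform: Affine
    crs: str = "EPSG:3035"
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not isinstance(self.transform, Affine):
            self.transform = Affine(*self.transform)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_ha(self) -> float:
        return cell_area_ha(self.transform)

    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata, finite) cells."""
        m = np.ones(self.shape, dtype=bool)
        if self.nodata is not None:
            m &= self.values != self.nodata
        if np.issubdtype(self.values.dtype, np.floating):
            m &= np.isfinite(self.values)
        return m

    def cell_centers(self):
        """(x, y) world coordinates of every cell centre, shaped like values."""
        rows, cols = np.meshgrid(
            np.arange(self.shape[0]), np.arange(self.shape[1]), indexing="ij"
        )
        return self.transform.xy(rows, cols)

    def is_coregistered_with(self, other: "Raster", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and np.allclose(self.transform, other.transform, atol=tol)
        )

    def with_values(self, values: np.ndarray, **kw) -> "Raster":
        return replace(self, values=values, **kw)


def _epsg_code(crs: str) -> int:
    c = str(crs).upper()
    if c.startswith("EPSG:"):
        return int(c.split(":")[1])
    return int(c)


def write_raster(raster: Raster, path: str | Path) -> Path:
    """Write a GeoTIFF with CRS, transform and nodata tags.

    Float rasters are written as float32 with deflate compression;
    integer rasters as int32.
    """
    t = raster.transform
    if t.b != 0 or t.d != 0:
        raise ValueError("only axis-aligned transforms can be written to GeoTIFF")
    values = raster.values
    if np.issubdtype(values.dtype, np.floating):
        values = values.astype(np.float32)
    else:
        values = values.astype(np.int32)

    epsg = _epsg_code(raster.crs)
    geographic = epsg == 4326
    keys = [
        (_KEY_MODEL_TYPE, 0, 1, 2 if geographic else 1),
        (_KEY_RASTER_TYPE, 0, 1, 1),
        (_KEY_GEOGRAPHIC_CS if geographic else _KEY_PROJECTED_CS, 0, 1, epsg),
    ]
    directory = [1, 1, 0, len(keys)]
    for k in keys:
        directory.extend(k)

    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (abs(t.a), abs(t.e), 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0), True),
        (_TAG_GEOKEYS, "H", len(directory), tuple(directory), True),
    ]
    if raster.nodata is not None:
        nd = f"{raster.nodata}"
        extratags.append((_TAG_GDAL_NODATA, "s", len(nd) + 1, nd, True))

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, values, extratags=extratags, compression="deflate")
    return path


def read_raster(path: str | Path) -> Raster:
    """Read a GeoTIFF written by :func:`write_raster` (or compatible)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        scale = tags.get(_TAG_PIXEL_SCALE)
        tie = tags.get(_TAG_TIEPOINT)
        if scale is None or tie is None:
            raise ValueError(f"{path}: missing georeferencing tags")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        ox, oy = float(tie.value[3]), float(tie.value[4])
        transform = Affine(sx, 0.0, ox, 0.0, -sy, oy)

        geokeys = tags.get(_TAG_GEOKEYS)
        if geokeys is None:
            raise ValueError(f"{path}: missing CRS (GeoKeyDirectory tag)")
        d = list(geokeys.value)
        epsg = None
        for i in range(4, len(d), 4):
            if d[i] in (_KEY_PROJECTED_CS, _KEY_GEOGRAPHIC_CS):
                epsg = d[i + 3]
        if epsg is None:
            raise ValueError(f"{path}: no EPSG code in GeoKeyDirectory")

        nodata = None
        nd_tag = tags.get(_TAG_GDAL_NODATA)
        if nd_tag is not None:
            text = nd_tag.value
            if isinstance(text, bytes):
                text = text.decode("ascii", "ignore")
            text = text.strip("\x00 ")
            if text:
                nodata = float(text) if np.issubdtype(values.dtype, np.floating) else int(float(text))

    return Raster(values=values, transform=transform, crs=f"EPSG:{epsg}", nodata=nodata)
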