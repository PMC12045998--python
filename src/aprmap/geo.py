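"""Georeferencing primitives: affine grid transforms and coordinate conversion.

Rasters in this package live on regular rectilinear grids described by an
:class:`Affine` transform (GDAL-style: world = A @ (col, row, 1)) plus a CRS
identifier. Two CRSs are supported natively:

* ``EPSG:3035`` — the ETRS89 Lambert azimuthal equal-area projection used for
  all European products (centre 52N 10E, false origin 4321000/3210000 m on
  the GRS80 ellipsoid). Being equal-area, every 250 m cell covers exactly
  6.25 ha regardless of location, which the mass-conservation logic relies on.
* ``EPSG:4326`` — geographic longitude/latitude in degrees, the native frame
  of coarse global application-rate grids.

The projection is implemented from the standard ellipsoidal Lambert
azimuthal equal-area formulas (authalic-latitude formulation) so that grids
in either frame can be compared through their cell centres.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

__all__ = [
    "Affine",
    "from_origin",
    "transform_points",
    "cell_area_ha",
    "laea_forward",
    "laea_inverse",
]


class Affine(NamedTuple):
    """Affine georeference ``x = a*col + b*row + c``, ``y = d*col + e*row + f``.

    ``(c, f)`` is the outer corner of the upper-left pixel; ``a`` is the pixel
    width and ``e`` the (negative) pixel height for north-up grids.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def xy(self, rows, cols, offset: str = "center"):
        """World coordinates of the given pixel indices (vectorised)."""
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        if offset == "center":
            rows = rows + 0.5
            cols = cols + 0.5
        elif offset != "corner":
            raise ValueError(f"unknown offset {offset!r}")
        x = self.a * cols + self.b * rows + self.c
        y = self.d * cols + self.e * rows + self.f
        return x, y

    def rowcol(self, x, y):
        """Fractional pixel indices containing the given world coordinates."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("degenerate affine transform")
        xc = x - self.c
        yc = y - self.f
        col = (self.e * xc - self.b * yc) / det
        row = (-self.d * xc + self.a * yc) / det
        return row, col

    def scale(self, factor: float) -> "Affine":
        """Transform of the grid coarsened by ``factor`` (same origin)."""
        return Affine(self.a * factor, self.b, self.c, self.d, self.e * factor, self.f)

    @property
    def pixel_width(self) -> float:
        return abs(self.a)

    @property
    def pixel_height(self) -> float:
        return abs(self.e)


def from_origin(west: float, north: float, xsize: float, ysize: float) -> Affine:
    """North-up transform from the upper-left corner and pixel sizes."""
    return Affine(xsize, 0.0, west, 0.0, -ysize, north)


def cell_area_ha(transform: Affine) -> float:
    """Area of one grid cell in hectares (projected, area-true CRS assumed)."""
    return abs(transform.a * transform.e - transform.b * transform.d) / 1.0e4


# --- ETRS89-LAEA (EPSG:3035) on GRS80 --------------------------------------

_A = 6378137.0
_F = 1.0 / 298.257222101
_E2 = _F * (2.0 - _F)
_E = math.sqrt(_E2)
_LAT0 = math.radians(52.0)
_LON0 = math.radians(10.0)
_FE = 4321000.0
_FN = 3210000.0


def _q(sin_phi):
    """Authalic-latitude auxiliary q(phi)."""
    esin = _E * sin_phi
    return (1.0 - _E2) * (
        sin_phi / (1.0 - _E2 * sin_phi**2)
        - (1.0 / (2.0 * _E)) * np.log((1.0 - esin) / (1.0 + esin))
    )


_QP = float(_q(1.0))
_BETA1 = math.asin(float(_q(math.sin(_LAT0))) / _QP)
_RQ = _A * math.sqrt(_QP / 2.0)
_M1 = math.cos(_LAT0) / math.sqrt(1.0 - _E2 * math.sin(_LAT0) ** 2)
_D = _A * _M1 / (_RQ * math.cos(_BETA1))
_SB1, _CB1 = math.sin(_BETA1), math.cos(_BETA1)


def laea_forward(lon, lat):
    """Project geographic coordinates (degrees) to EPSG:3035 metres."""
    lam = np.radians(np.asarray(lon, dtype=float)) - _LON0
    phi = np.radians(np.asarray(lat, dtype=float))
    beta = np.arcsin(np.clip(_q(np.sin(phi)) / _QP, -1.0, 1.0))
    sb, cb = np.sin(beta), np.cos(beta)
    denom = 1.0 + _SB1 * sb + _CB1 * cb * np.cos(lam)
    b = _RQ * np.sqrt(2.0 / denom)
    x = _FE + b * _D * cb * np.sin(lam)
    y = _FN + (b / _D) * (_CB1 * sb - _SB1 * cb * np.cos(lam))
    return x, y


def laea_inverse(x, y):
    """Inverse of :func:`laea_forward`; returns (lon, lat) in degrees."""
    xp = (np.asarray(x, dtype=float) - _FE) / _D
    yp = _D * (np.asarray(y, dtype=float) - _FN)
    rho = np.hypot(xp, yp)
    ce = 2.0 * np.arcsin(np.clip(rho / (2.0 * _RQ), -1.0, 1.0))
    sin_ce, cos_ce = np.sin(ce), np.cos(ce)
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_beta = np.where(
            rho == 0.0, _SB1, cos_ce * _SB1 + yp * sin_ce * _CB1 / np.where(rho == 0, 1, rho)
        )
    beta = np.arcsin(np.clip(sin_beta, -1.0, 1.0))
    lam = np.arctan2(xp * sin_ce, rho * _CB1 * cos_ce - yp * _SB1 * sin_ce)
    # authalic -> geodetic latitude series
    e2, e4, e6 = _E2, _E2**2, _E2**3
    phi = (
        beta
        + (e2 / 3.0 + 31.0 * e4 / 180.0 + 517.0 * e6 / 5040.0) * np.sin(2.0 * beta)
        + (23.0 * e4 / 360.0 + 251.0 * e6 / 3780.0) * np.sin(4.0 * beta)
        + (761.0 * e6 / 45360.0) * np.sin(6.0 * beta)
    )
    return np.degrees(lam + _LON0), np.degrees(phi)


_GEOGRAPHIC = {"EPSG:4326", "epsg:4326", "4326"}
_LAEA = {"EPSG:3035", "epsg:3035", "3035"}


def _norm(crs: str) -> str:
    c = str(crs)
    if c in _GEOGRAPHIC:
        return "EPSG:4326"
    if c in _LAEA:
        return "EPSG:3035"
    return c


def transform_points(src_crs: str, dst_crs: str, x, y):
    """Transform point coordinates between the two supported CRSs.

    Identity for equal CRSs (any identifier); otherwise only the
    EPSG:4326 <-> EPSG:3035 pair is supported.
    """
    src, dst = _norm(src_crs), _norm(dst_crs)
    if src == dst:
        return np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if src == "EPSG:4326" and dst == "EPSG:3035":
        return laea_forward(x, y)
    if src == "EPSG:3035" and dst == "EPSG:4326":
        return laea_inverse(x, y)
    raise ValueError(f"unsupported CRS pair {src_crs!r} -> {dst_crs!r}")
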