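"""Projection of coarse application-rate grids and first-guess mass accumulation.

A coarse per-ingredient grid (typically in geographic coordinates) is pushed
onto the fine projected crop grid by nearest-neighbour lookup of cell
centres, masked by country-level authorizations, and accumulated into the
first-guess applied mass per (major group, calibration crop, country):

    m~_mg(crop, country) = sum over ais in mg, pixels with an applicable
                           crop class of APR~_ai * cell_area

with the cell area taken from the projected transform (6.25 ha for 250 m
cells in the equal-area CRS).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .domain import (
    AuthorizationTable,
    PesticideTaxonomy,
    pcg_class_of_code,
    to_calibration_crop,
)
from .geo import transform_points
from .raster import Raster

logger = logging.getLogger("aprmap.projection")

__all__ = [
    "project_apr",
    "apply_authorization",
    "first_guess_mass",
    "mass_table",
]

MASS_COLUMNS = ["major_group", "crop", "country", "mass_kg"]


def mass_table(rows: Iterable[tuple[str, str, str, float]]) -> pd.DataFrame:
    """Build a mass table (major_group, crop, country, mass_kg), sorted by key."""
    df = pd.DataFrame(rows, columns=MASS_COLUMNS)
    if (df["mass_kg"] < 0).any():
        raise ValueError("negative mass")
    if df.duplicated(subset=MASS_COLUMNS[:3]).any():
        raise ValueError("duplicate (major_group, crop, country) keys")
    return df.sort_values(MASS_COLUMNS[:3], ignore_index=True)


def project_apr(
    coarse: Raster,
    target: Raster,
    max_extrapolation_cells: float = 0.5,
) -> Raster:
    """Nearest-neighbour projection of a coarse grid onto the target grid.

    Each target cell takes the value of the coarse cell whose centre is
    nearest to the target cell centre, after transforming centres into the
    coarse CRS. Target centres farther than ``max_extrapolation_cells``
    coarse cells outside the coarse extent raise an error; coarse nodata
    propagates.
    """
    tx, ty = target.cell_centers()
    cx, cy = transform_points(target.crs, coarse.crs, tx.ravel(), ty.ravel())
    row_f, col_f = coarse.transform.rowcol(cx, cy)

    nrows, ncols = coarse.shape
    slack = float(max_extrapolation_cells)
    if (
        (row_f < -slack).any()
        or (row_f > nrows + slack).any()
        or (col_f < -slack).any()
        or (col_f > ncols + slack).any()
    ):
        raise ValueError(
            "target grid extends beyond the coarse grid by more than "
            f"{slack} coarse cells; extents are effectively disjoint"
        )
    rows = np.clip(np.floor(row_f).astype(int), 0, nrows - 1)
    cols = np.clip(np.floor(col_f).astype(int), 0, ncols - 1)
    values = coarse.values[rows, cols].reshape(target.shape)
    return Raster(
        values=values,
        transform=target.transform,
        crs=target.crs,
        nodata=coarse.nodata,
    )


def apply_authorization(
    fine: Raster,
    ai_name: str,
    auth: AuthorizationTable,
    countries: Raster,
    country_names: Mapping[int, str],
) -> Raster:
    """Zero out application rates in countries where the ingredient is banned.

    ``countries`` holds integer country ids whose names are given by
    ``country_names``; a missing authorization record is an error (the table
    must be explicit, absence of a record is not a ban).
    """
    if fine.values.shape != countries.values.shape:
        raise ValueError("country raster is not co-registered with the rate grid")
    out = fine.values.astype(float).copy()
    for cid, name in country_names.items():
        in_country = countries.values == cid
        if not in_country.any():
            continue
        if not auth.is_approved(ai_name, name):
            if fine.nodata is not None:
                in_country = in_country & (fine.values != fine.nodata)
            out[in_country] = 0.0
    return fine.with_values(out)


def first_guess_mass(
    fine_by_ai: Mapping[str, Raster],
    crops: Raster,
    countries: Raster,
    country_names: Mapping[int, str],
    tax: PesticideTaxonomy,
    cell_area_ha: float | None = None,
) -> pd.DataFrame:
    """First-guess applied mass per (major group, calibration crop, country).

    For every active ingredient, pixels whose mapped crop class is in the
    ingredient's applicable set contribute ``rate * cell_area``; the
    contribution lands in the ingredient's major group with the pixel's crop
    pooled to Corn/Wheat/AOC.
    """
    area = crops.cell_area_ha if cell_area_ha is None else float(cell_area_ha)
    if area <= 0:
        raise ValueError("cell area must be positive")

    crop_valid = crops.mask()
    accum: dict[tuple[str, str, str], float] = {}
    for ai_name, grid in fine_by_ai.items():
        if grid.values.shape != crops.values.shape:
            raise ValueError(f"{ai_name}: rate grid not co-registered with crop raster")
        rec = tax.record(ai_name)
        rate = np.asarray(grid.values, dtype=float)
        valid = crop_valid.copy()
        if grid.nodata is not None:
            valid &= grid.values != grid.nodata
        valid &= np.isfinite(rate)
        for cid, cname in country_names.items():
            sel_country = valid & (countries.values == cid)
            if not sel_country.any():
                continue
            for code in np.unique(crops.values[sel_country]):
                crop_class = pcg_class_of_code(int(code))
                if crop_class not in rec.applicable_crops:
                    continue
                sel = sel_country & (crops.values == code)
                mass = float(rate[sel].sum()) * area
                key = (rec.major_group, to_calibration_crop(crop_class), cname)
                accum[key] = accum.get(key, 0.0) + mass

    return mass_table([(mg, cr, co, m) for (mg, cr, co), m in accum.items()])
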