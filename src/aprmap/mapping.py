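"""Scenario map generation: correction factors and corrected rate rasters.

Scenario masses are turned into multiplicative correction factors
K = m_S / m~ per (major group, calibration crop, country, scenario), and
each first-guess rate pixel is multiplied by the factor matching its crop
class, country and the ingredient's major group. Because the grid is
equal-area, this construction conserves mass exactly: summing the corrected
rates times the cell area over a (crop, country) zone returns the scenario
mass for that key.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .domain import (
    PCG_CODES,
    PCG_NODATA,
    PesticideTaxonomy,
    RegionAssignment,
    pcg_class_of_code,
    to_calibration_crop,
)
from .raster import Raster, write_raster

logger = logging.getLogger("aprmap.mapping")

__all__ = ["correction_factors", "apply_correction", "write_scenario_maps", "SCENARIOS"]

SCENARIOS = ("Low", "Median", "High")
_SCENARIO_COLUMN = {"Low": "m_low", "Median": "m_median", "High": "m_high"}


def correction_factors(
    scenarios: pd.DataFrame, m_tilde: pd.DataFrame
) -> pd.DataFrame:
    """K = m_S / m~ per (major_group, crop, country, scenario).

    ``scenarios`` carries columns m_low/m_median/m_high (one row per key);
    the result has one row per (key, scenario) with the factor K.
    """
    merged = scenarios.merge(
        m_tilde.rename(columns={"mass_kg": "m_tilde"}),
        on=["major_group", "crop", "country"],
        how="left",
    )
    if merged["m_tilde"].isna().any():
        missing = merged.loc[merged["m_tilde"].isna(), ["major_group", "crop", "country"]]
        raise ValueError(f"first-guess mass missing for keys:\n{missing}")
    bad = merged["m_tilde"] <= 0
    if bad.any():
        rows = merged.loc[bad]
        nonzero = rows[[c for c in _SCENARIO_COLUMN.values()]].gt(0).any(axis=1)
        if nonzero.any():
            key = rows.loc[nonzero].iloc[0]
            raise ValueError(
                "zero first-guess mass with nonzero scenario mass for "
                f"({key['major_group']}, {key['crop']}, {key['country']})"
            )
    rows = []
    for scen, col in _SCENARIO_COLUMN.items():
        part = merged[["major_group", "crop", "country"]].copy()
        part["scenario"] = scen
        part["K"] = merged[col] / merged["m_tilde"]
        rows.append(part)
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(
        ["major_group", "crop", "country", "scenario"], ignore_index=True
    )


def _factor_lookup(
    K: pd.DataFrame, regions: RegionAssignment
) -> tuple[dict, dict]:
    """Direct (mg, crop, country, scenario) -> K dict plus region-average
    fallback (mg, crop, region, scenario) -> mean K."""
    direct = {
        (r.major_group, r.crop, r.country, r.scenario): float(r.K)
        for r in K.itertuples()
    }
    with_region = K.assign(region=K["country"].map(regions.region))
    fallback = (
        with_region.groupby(["major_group", "crop", "region", "scenario"])["K"]
        .mean()
        .to_dict()
    )
    return direct, fallback


def apply_correction(
    apr_tilde: Raster,
    ai_name: str,
    scenario: str,
    K: pd.DataFrame,
    crops: Raster,
    countries: Raster,
    country_names: Mapping[int, str],
    tax: PesticideTaxonomy,
    regions: RegionAssignment,
) -> Raster:
    """Scenario rate raster: per-pixel K times the first-guess rate.

    The factor is resolved per (major group of the ingredient, pixel crop
    class pooled to Corn/Wheat/AOC, pixel country). Keys without a factor
    (no reference data survived preparation) fall back to the mean factor of
    the same region, crop and scenario, with a logged warning. Pixels of
    excluded crop classes are nodata.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if crops.values.shape != apr_tilde.values.shape or crops.values.shape != countries.values.shape:
        raise ValueError("rasters are not co-registered")
    rec = tax.record(ai_name)
    mg = rec.major_group
    direct, fallback = _factor_lookup(K, regions)

    nodata = apr_tilde.nodata if apr_tilde.nodata is not None else -9999.0
    out = np.full(apr_tilde.shape, nodata, dtype=np.float64)
    valid = crops.mask() & (crops.values != PCG_NODATA)
    # the ingredient is only applied on its applicable crop classes
    applicable = [PCG_CODES[c] for c in rec.applicable_crops]
    valid &= np.isin(crops.values, applicable)
    if apr_tilde.nodata is not None:
        valid &= apr_tilde.values != apr_tilde.nodata

    n_fallback = 0
    for cid, cname in country_names.items():
        sel_c = valid & (countries.values == cid)
        if not sel_c.any():
            continue
        region = regions.region(cname)
        for code in np.unique(crops.values[sel_c]):
            crop = to_calibration_crop(pcg_class_of_code(int(code)))
            key = (mg, crop, cname, scenario)
            k = direct.get(key)
            if k is None:
                k = fallback.get((mg, crop, region, scenario))
                if k is None:
                    raise KeyError(
                        f"no correction factor (direct or regional) for {key}"
                    )
                n_fallback += 1
            sel = sel_c & (crops.values == code)
            out[sel] = k * apr_tilde.values[sel]
    if n_fallback:
        logger.warning(
            "%s/%s: %d (crop, country) zones used region-average factors",
            ai_name, scenario, n_fallback,
        )
    return apr_tilde.with_values(out, nodata=nodata)


def write_scenario_maps(
    grids: Mapping[tuple[str, str], Raster],
    out_dir: str | Path,
    manifest_extra: dict | None = None,
) -> list[Path]:
    """Write one GeoTIFF per (ingredient, scenario) plus a JSON manifest.

    Files are named ``<ai>_<scenario>.tif`` with spaces and commas in the
    ingredient name replaced by hyphens.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for (ai_name, scenario), grid in sorted(grids.items()):
        safe = ai_name.replace(" ", "-").replace(",", "-").replace("/", "-")
        path = out_dir / f"{safe}_{scenario}.tif"
        write_raster(grid.with_values(grid.values.astype(np.float32)), path)
        written.append(path)
    manifest = {
        "files": [p.name for p in written],
        **(manifest_extra or {}),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return written
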