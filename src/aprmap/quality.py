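"""Data-quality index and validation ratios.

The quality index scores the agreement between the calibrated mass m^ and
the reference mass m* through the symmetric relative residual

    QI = 1 - |m^ - m*| / (m^ + m*),

which is 1 for perfect agreement and 0 when one of the masses vanishes.
Keys without reference data inherit the unweighted mean QI of the same
(region, crop) donors. QI is shared by every ingredient of a major group
and is rendered as a raster on the application-rate grid. The validation
ratio R = m_S / m* compares scenario masses against the reference, ideally
equal to one.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .domain import (
    PCG_NODATA,
    PesticideTaxonomy,
    RegionAssignment,
    pcg_class_of_code,
    to_calibration_crop,
)
from .raster import Raster

logger = logging.getLogger("aprmap.quality")

__all__ = [
    "quality_index",
    "qi_table",
    "qi_with_fallback",
    "qi_raster",
    "validation_ratio",
]


def quality_index(m_hat: float, m_star: float) -> float:
    """QI = 1 - |m^ - m*|/(m^ + m*) for nonnegative masses with positive sum."""
    if m_hat < 0 or m_star < 0:
        raise ValueError("masses must be nonnegative")
    total = m_hat + m_star
    if total <= 0:
        raise ValueError("QI undefined for two zero masses")
    return 1.0 - abs(m_hat - m_star) / total


def qi_table(m_hat: pd.DataFrame, m_star: pd.DataFrame) -> pd.DataFrame:
    """Direct QI per (major_group, crop, country) on overlapping keys."""
    merged = m_hat.merge(
        m_star, on=["major_group", "crop", "country"], suffixes=("_hat", "_star"),
        how="inner",
    )
    merged["qi"] = [
        quality_index(r.mass_kg_hat, r.mass_kg_star) for r in merged.itertuples()
    ]
    merged["flag"] = "direct"
    return merged[["major_group", "crop", "country", "qi", "flag"]].sort_values(
        ["major_group", "crop", "country"], ignore_index=True
    )


def qi_with_fallback(
    direct: pd.DataFrame,
    needed_keys: pd.DataFrame,
    regions: RegionAssignment,
) -> pd.DataFrame:
    """Extend direct QI values to all needed keys via region/crop averages.

    ``needed_keys`` lists the (major_group, crop, country) keys that must be
    covered (typically every key of the first-guess mass table). Keys absent
    from ``direct`` receive the unweighted mean of the direct QI of the same
    (major group, region, crop), flagged ``region_fallback``; a direct value
    is never overwritten. Missing donors are an error.
    """
    direct = direct.copy()
    have = {(r.major_group, r.crop, r.country) for r in direct.itertuples()}
    donors = direct.assign(region=direct["country"].map(regions.region))
    donor_means = donors.groupby(["major_group", "crop", "region"])["qi"].mean()

    rows = []
    gaps = []
    for r in needed_keys[["major_group", "crop", "country"]].drop_duplicates().itertuples():
        key = (r.major_group, r.crop, r.country)
        if key in have:
            continue
        region = regions.region(r.country)
        try:
            qi = float(donor_means.loc[(r.major_group, r.crop, region)])
        except KeyError:
            gaps.append((r.major_group, r.crop, region))
            continue
        rows.append((r.major_group, r.crop, r.country, qi, "region_fallback"))
    if gaps:
        raise ValueError(
            f"no donor QI entries for (major_group, crop, region) groups: {sorted(set(gaps))}"
        )
    if not rows:
        return direct.sort_values(["major_group", "crop", "country"], ignore_index=True)
    logger.info("filled %d QI keys by region fallback", len(rows))
    out = pd.concat(
        [direct, pd.DataFrame(rows, columns=direct.columns)], ignore_index=True
    )
    return out.sort_values(["major_group", "crop", "country"], ignore_index=True)


def qi_raster(
    qi: pd.DataFrame,
    crops: Raster,
    countries: Raster,
    country_names: Mapping[int, str],
    tax: PesticideTaxonomy,
    ai_name: str,
    nodata: float = -9999.0,
) -> Raster:
    """Per-pixel QI of (major group of the ingredient, crop class, country).

    Nodata outside mapped crop pixels; a key still missing after fallback is
    an error.
    """
    if crops.values.shape != countries.values.shape:
        raise ValueError("rasters are not co-registered")
    mg = tax.major_group_of(ai_name)
    lookup = {
        (r.major_group, r.crop, r.country): float(r.qi) for r in qi.itertuples()
    }
    out = np.full(crops.shape, nodata, dtype=np.float64)
    valid = crops.mask() & (crops.values != PCG_NODATA)
    for cid, cname in country_names.items():
        sel_c = valid & (countries.values == cid)
        if not sel_c.any():
            continue
        for code in np.unique(crops.values[sel_c]):
            crop = to_calibration_crop(pcg_class_of_code(int(code)))
            key = (mg, crop, cname)
            if key not in lookup:
                raise KeyError(f"no QI value for {key}")
            out[sel_c & (crops.values == code)] = lookup[key]
    return Raster(out, crops.transform, crops.crs, nodata=nodata)


def validation_ratio(
    scenarios: pd.DataFrame, m_star: pd.DataFrame
) -> pd.DataFrame:
    """R = m_S / m* per (major_group, crop, country, scenario).

    Keys with zero or missing reference mass are skipped with a log message.
    """
    merged = scenarios.merge(
        m_star.rename(columns={"mass_kg": "m_star"}),
        on=["major_group", "crop", "country"],
        how="inner",
    )
    bad = merged["m_star"] <= 0
    if bad.any():
        logger.warning("skipped %d validation keys with zero reference mass", int(bad.sum()))
        merged = merged[~bad]
    rows = []
    for scen, col in (("Low", "m_low"), ("Median", "m_median"), ("High", "m_high")):
        part = merged[["major_group", "crop", "country"]].copy()
        part["scenario"] = scen
        part["R"] = merged[col] / merged["m_star"]
        rows.append(part)
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(
        ["major_group", "crop", "country", "scenario"], ignore_index=True
    )


def plot_validation_ratios(ratios: pd.DataFrame, ax=None):
    """Optional bar chart of validation-ratio ranges per country (needs
    matplotlib; purely illustrative)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    wide = ratios.pivot_table(
        index=["major_group", "crop", "country"], columns="scenario", values="R"
    )
    x = np.arange(len(wide))
    ax.vlines(x, wide["Low"], wide["High"], color="c", lw=4, alpha=0.6)
    ax.plot(x, wide["Median"], "k.", ms=5)
    ax.axhline(1.0, color="r", lw=0.8)
    ax.set_yscale("log")
    ax.set_ylabel("R = m_S / m*")
    ax.set_xticks(x)
    ax.set_xticklabels(["/".join(map(str, t)) for t in wide.index], rotation=90, fontsize=6)
    return ax
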