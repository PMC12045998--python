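"""Assembly of the reference (calibration) mass dataset.

Statistical-office usage records arrive as (country, crop label, chemical
class, year, mass) rows. They are turned into the calibration table
m*(major group, crop, country) in four ordered steps:

a. average over the reporting window (2015-2020 by default, centring the
   sparse series on the reference year) — missing years are skipped, not
   zero-filled;
b. keep only chemical classes that contain at least one mapped active
   ingredient;
c. pool crop labels into the Corn/Wheat/AOC calibration classes;
d. drop masses below the retention threshold (100 kg).

Coverage fractions F* = (selected mass)/(total major-group mass) quantify
how much of the reported usage the retained classes represent; ratios above
one (asynchronous reporting artefacts) are discarded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .domain import PesticideTaxonomy

logger = logging.getLogger("aprmap.calibration_prep")

__all__ = [
    "average_years",
    "select_classes",
    "map_crops_to_calibration",
    "filter_small",
    "coverage_fractions",
    "prepare_reference",
    "WHEAT_LABELS",
    "CORN_LABELS",
    "DEFAULT_WINDOW",
    "DEFAULT_THRESHOLD_KG",
]

RECORD_COLUMNS = ["country", "crop_label", "chem_class_code", "year", "mass_kg"]

WHEAT_LABELS = frozenset(
    {
        "Common spring wheat and spelt",
        "Common wheat and spelt",
        "Common winter wheat and spelt",
        "Durum wheat",
    }
)
CORN_LABELS = frozenset({"Grain maize and corn-cob-mix", "Green maize"})

DEFAULT_WINDOW = range(2015, 2021)
DEFAULT_THRESHOLD_KG = 100.0


def average_years(records: pd.DataFrame, window=DEFAULT_WINDOW) -> pd.DataFrame:
    """Mean mass per (country, crop label, chemical class) over the window.

    Only years inside the window contribute; a key reported in a subset of
    the years is averaged over the years it has (sparse series are not
    zero-filled).
    """
    years = list(window)
    if len(years) == 0:
        raise ValueError("empty averaging window")
    df = records[records["year"].isin(years)]
    out = (
        df.groupby(["country", "crop_label", "chem_class_code"], as_index=False)[
            "mass_kg"
        ].mean()
    )
    return out


def select_classes(records: pd.DataFrame, tax: PesticideTaxonomy) -> pd.DataFrame:
    """Keep records whose chemical class contains a mapped active ingredient."""
    keep = records["chem_class_code"].isin(tax.chem_class_codes)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d records from unmapped chemical classes", dropped)
    return records[keep].reset_index(drop=True)


def _calibration_crop(label: str) -> str:
    if label in WHEAT_LABELS:
        return "Wheat"
    if label in CORN_LABELS:
        return "Corn"
    return "AOC"


def map_crops_to_calibration(records: pd.DataFrame) -> pd.DataFrame:
    """Pool crop labels into Corn/Wheat/AOC and sum masses within keys.

    The chemical-class code is replaced by the major group (its leading
    letter) at this stage, so the output is keyed
    (major_group, crop, country).
    """
    df = records.copy()
    df["crop"] = df["crop_label"].map(_calibration_crop)
    df["major_group"] = df["chem_class_code"].str[0]
    out = (
        df.groupby(["major_group", "crop", "country"], as_index=False)["mass_kg"].sum()
    )
    return out.sort_values(["major_group", "crop", "country"], ignore_index=True)


def filter_small(
    records: pd.DataFrame, threshold_kg: float = DEFAULT_THRESHOLD_KG
) -> pd.DataFrame:
    """Drop rows with mass strictly below the threshold (boundary retained)."""
    keep = records["mass_kg"] >= threshold_kg
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d reference rows below %.0f kg", dropped, threshold_kg)
    return records[keep].reset_index(drop=True)


def prepare_reference(
    records: pd.DataFrame,
    tax: PesticideTaxonomy,
    window=DEFAULT_WINDOW,
    threshold_kg: float = DEFAULT_THRESHOLD_KG,
) -> pd.DataFrame:
    """Full preparation pipeline a-d; returns m*(major_group, crop, country)."""
    out = average_years(records, window)
    out = select_classes(out, tax)
    out = map_crops_to_calibration(out)
    return filter_small(out, threshold_kg)


def coverage_fractions(
    selected: pd.DataFrame, totals: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Coverage F* per key and mass-weighted per-group aggregates.

    ``selected`` is the prepared reference table; ``totals`` carries the full
    major-group masses on the same (major_group, crop, country) keys. Keys
    with F* > 1 are discarded (and logged); the aggregate per major group is
    the total-mass-weighted mean of the retained F*.
    """
    merged = selected.merge(
        totals,
        on=["major_group", "crop", "country"],
        suffixes=("_selected", "_total"),
        how="inner",
    )
    zero_total = merged["mass_kg_total"] <= 0
    if zero_total.any():
        logger.warning(
            "dropped %d coverage keys with zero total mass", int(zero_total.sum())
        )
        merged = merged[~zero_total]
    merged = merged.assign(coverage=merged["mass_kg_selected"] / merged["mass_kg_total"])
    over = merged["coverage"] > 1.0
    if over.any():
        logger.warning("disregarded %d coverage keys with F* > 1", int(over.sum()))
    merged = merged[~over].reset_index(drop=True)

    def _weighted(g: pd.DataFrame) -> float:
        return float(np.average(g["coverage"], weights=g["mass_kg_total"]))

    aggregates = merged.groupby("major_group").apply(_weighted, include_groups=False)
    table = merged[["major_group", "crop", "country", "coverage"]]
    return table, aggregates
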