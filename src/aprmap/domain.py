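"""Controlled vocabularies: crop classes, pesticide taxonomy, regions, authorizations.

The mapping pipeline works with eight crop classes (Corn, Soybean, Wheat,
Rice, VegFru, OrcGra, PasHay, Other) obtained by cross-walking a fine
European crop map to the cropping systems of the coarse global
application-rate product; Cotton and Alfalfa cannot be separated from
composite land-cover labels and are excluded. Active ingredients are
organised by EUROSTAT chemical class (codes like ``H01_01``) nested in four
major groups: herbicides (H), fungicides (F), insecticides (I) and other
plant-protection products (Z). Countries are partitioned into southern
(SEU), central (CEU) and northern (NEU) Europe for the calibration model.

The reference tables are shipped as CSV package data and loaded through the
functions below; users may substitute their own files with the same columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger("aprmap.domain")

__all__ = [
    "CROP_CLASSES",
    "CALIBRATION_CROPS",
    "EXCLUDED",
    "REGIONS",
    "PCG_CODES",
    "PCG_NODATA",
    "CropClassMap",
    "PesticideTaxonomy",
    "TaxonomyRecord",
    "RegionAssignment",
    "AuthorizationTable",
    "load_crop_class_map",
    "load_taxonomy",
    "load_regions",
    "load_authorizations",
    "count_active_ingredients",
    "assign_region",
    "map_crop_label",
    "pcg_class_of_code",
    "ValidationError",
    "to_calibration_crop",
    "published_calibration",
]

#: The eight mapped crop classes (Cotton and Alfalfa excluded).
CROP_CLASSES: tuple[str, ...] = (
    "Corn", "Soybean", "Wheat", "Rice", "VegFru", "OrcGra", "PasHay", "Other",
)

#: Crop keys used by the calibration model: Corn, Wheat, and everything else
#: pooled into "Any Other Crop".
CALIBRATION_CROPS: tuple[str, ...] = ("Corn", "Wheat", "AOC")

EXCLUDED = "EXCLUDED"

REGIONS: tuple[str, ...] = ("SEU", "CEU", "NEU")

#: Integer codes used for aggregated crop-class rasters (0 reserved as nodata).
PCG_CODES: dict[str, int] = {c: i + 1 for i, c in enumerate(CROP_CLASSES)}
PCG_NODATA = 0

_CODE_TO_CLASS = {v: k for k, v in PCG_CODES.items()}


def pcg_class_of_code(code: int) -> str:
    return _CODE_TO_CLASS[code]


def to_calibration_crop(crop_class: str) -> str:
    """Pool the eight mapped classes into the Corn/Wheat/AOC calibration key."""
    if crop_class in ("Corn", "Wheat"):
        return crop_class
    if crop_class in CROP_CLASSES or crop_class == "AOC":
        return "AOC"
    raise ValueError(f"unknown crop class {crop_class!r}")


class ValidationError(ValueError):
    """Raised when a vocabulary file violates its invariants."""


def _data_path(name: str):
    return resources.files("aprmap.data").joinpath(name)


# --- crop class map ---------------------------------------------------------

@dataclass(frozen=True)
class CropClassMap:
    """Crosswalk from fused crop-map raster codes to the mapped crop classes."""

    entries: dict[int, tuple[str, str]]  # code -> (source_label, target_class)

    def target_class(self, code: int) -> str:
        """Mapped class for a raster code; unlisted codes are EXCLUDED."""
        entry = self.entries.get(int(code))
        if entry is None:
            logger.warning("raster code %s not in crop class map; treated as EXCLUDED", code)
            return EXCLUDED
        return entry[1]

    @property
    def mapped_classes(self) -> set[str]:
        return {t for _, t in self.entries.values() if t != EXCLUDED}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, lbl, t) for c, (lbl, t) in sorted(self.entries.items())],
            columns=["source_code", "source_label", "target_class"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_crop_class_map(path: str | Path | None = None) -> CropClassMap:
    """Load the code crosswalk (packaged table when ``path`` is None)."""
    src = path if path is not None else _data_path("crop_classes.csv")
    df = pd.read_csv(src)
    required = {"source_code", "source_label", "target_class"}
    if not required.issubset(df.columns):
        raise ValidationError(f"crop class map needs columns {sorted(required)}")
    if df["source_code"].duplicated().any():
        dups = df.loc[df["source_code"].duplicated(), "source_code"].tolist()
        raise ValidationError(f"duplicate source codes {dups}")
    bad = set(df["target_class"]) - set(CROP_CLASSES) - {EXCLUDED}
    if bad:
        raise ValidationError(f"unknown target classes {sorted(bad)}")
    entries = {
        int(r.source_code): (str(r.source_label), str(r.target_class))
        for r in df.itertuples()
    }
    return CropClassMap(entries=entries)


def map_crop_label(code: int, m: CropClassMap) -> str:
    return m.target_class(code)


# --- pesticide taxonomy -----------------------------------------------------

@dataclass(frozen=True)
class TaxonomyRecord:
    ai_name: str
    chem_class_code: str
    chem_class_name: str
    major_group: str
    applicable_crops: frozenset[str]


@dataclass(frozen=True)
class PesticideTaxonomy:
    records: tuple[TaxonomyRecord, ...]

    @property
    def ai_names(self) -> list[str]:
        return [r.ai_name for r in self.records]

    @property
    def chem_class_codes(self) -> set[str]:
        return {r.chem_class_code for r in self.records}

    @property
    def major_groups(self) -> set[str]:
        return {r.major_group for r in self.records}

    def record(self, ai_name: str) -> TaxonomyRecord:
        for r in self.records:
            if r.ai_name == ai_name:
                return r
        raise KeyError(ai_name)

    def major_group_of(self, ai_name: str) -> str:
        return self.record(ai_name).major_group

    def subset(self, ai_names) -> "PesticideTaxonomy":
        keep = set(ai_names)
        missing = keep - set(self.ai_names)
        if missing:
            raise KeyError(f"unknown active ingredients {sorted(missing)}")
        return PesticideTaxonomy(tuple(r for r in self.records if r.ai_name in keep))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            if r.applicable_crops == frozenset(CROP_CLASSES):
                crops = "ALL"
            else:
                crops = ";".join(c for c in CROP_CLASSES if c in r.applicable_crops)
            rows.append((r.ai_name, r.chem_class_code, r.chem_class_name, r.major_group, crops))
        return pd.DataFrame(
            rows, columns=["ai_name", "chem_class_code", "chem_class_name", "major_group", "crops"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_taxonomy(path: str | Path | None = None) -> PesticideTaxonomy:
    """Load the active-ingredient taxonomy (packaged table when ``path`` is None).

    Columns: ai_name, chem_class_code, chem_class_name, major_group, crops
    (semicolon-separated crop classes or the token ALL).
    """
    src = path if path is not None else _data_path("taxonomy.csv")
    df = pd.read_csv(src)
    required = {"ai_name", "chem_class_code", "chem_class_name", "major_group", "crops"}
    if not required.issubset(df.columns):
        raise ValidationError(f"taxonomy needs columns {sorted(required)}")
    if len(df) == 0:
        raise ValidationError("taxonomy file is empty")
    if df["ai_name"].duplicated().any():
        dups = df.loc[df["ai_name"].duplicated(), "ai_name"].tolist()
        raise ValidationError(f"duplicate active ingredients {dups}")

    records = []
    class_group: dict[str, str] = {}
    for r in df.itertuples():
        mg = str(r.major_group).strip()
        code = str(r.chem_class_code).strip()
        if not code.startswith(mg):
            raise ValidationError(
                f"{r.ai_name}: chemical class {code} does not match major group {mg}"
            )
        if class_group.setdefault(code, mg) != mg:
            raise ValidationError(f"chemical class {code} mapped to two major groups")
        token = str(r.crops).strip()
        if token == "ALL":
            crops = frozenset(CROP_CLASSES)
        else:
            crops = frozenset(t.strip() for t in token.split(";") if t.strip())
            bad = crops - set(CROP_CLASSES)
            if bad:
                raise ValidationError(f"{r.ai_name}: unknown crop tokens {sorted(bad)}")
            if not crops:
                raise ValidationError(f"{r.ai_name}: empty crop list")
        records.append(
            TaxonomyRecord(str(r.ai_name), code, str(r.chem_class_name), mg, crops)
        )
    return PesticideTaxonomy(tuple(records))


def count_active_ingredients(tax: PesticideTaxonomy, exclude_groups=()) -> int:
    """Number of distinct active ingredients outside the excluded major groups."""
    excluded = set(exclude_groups)
    return len({r.ai_name for r in tax.records if r.major_group not in excluded})


# --- regions ----------------------------------------------------------------

@dataclass(frozen=True)
class RegionAssignment:
    """Country -> SEU/CEU/NEU partition of the study countries."""

    mapping: dict[str, str]

    def region(self, country: str) -> str:
        try:
            return self.mapping[country]
        except KeyError:
            raise KeyError(
                f"country {country!r} has no region assignment; "
                "supply an override if it is outside the shipped list"
            ) from None

    @property
    def countries(self) -> list[str]:
        return sorted(self.mapping)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.mapping.items()), columns=["country", "region"]
        )


def load_regions(
    path: str | Path | None = None, overrides: dict[str, str] | None = None
) -> RegionAssignment:
    """Load the country->region table; ``overrides`` may add countries
    (e.g. Croatia, which the shipped list omits) or reassign them."""
    src = path if path is not None else _data_path("regions.csv")
    df = pd.read_csv(src)
    if not {"country", "region"}.issubset(df.columns):
        raise ValidationError("regions file needs columns country, region")
    mapping = {str(r.country): str(r.region) for r in df.itertuples()}
    if overrides:
        mapping.update(overrides)
    bad = set(mapping.values()) - set(REGIONS)
    if bad:
        raise ValidationError(f"unknown regions {sorted(bad)}")
    return RegionAssignment(mapping)


def assign_region(country: str, regions: RegionAssignment | None = None) -> str:
    if regions is None:
        regions = load_regions()
    return regions.region(country)


# --- authorizations ---------------------------------------------------------

@dataclass(frozen=True)
class AuthorizationTable:
    """(active ingredient, country) -> approved flag; missing pairs are errors."""

    approved: dict[tuple[str, str], bool]

    def is_approved(self, ai_name: str, country: str) -> bool:
        key = (ai_name, country)
        if key not in self.approved:
            raise KeyError(f"no authorization record for {ai_name!r} in {country!r}")
        return self.approved[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, c, int(v)) for (a, c), v in sorted(self.approved.items())]
        return pd.DataFrame(rows, columns=["ai_name", "country", "approved"])


def load_authorizations(path: str | Path) -> AuthorizationTable:
    df = pd.read_csv(path)
    if not {"ai_name", "country", "approved"}.issubset(df.columns):
        raise ValidationError("authorizations file needs columns ai_name, country, approved")
    approved = {
        (str(r.ai_name), str(r.country)): bool(int(r.approved)) for r in df.itertuples()
    }
    if len(approved) != len(df):
        raise ValidationError("duplicate (ai_name, country) pairs in authorizations")
    return AuthorizationTable(approved)


# --- published calibration estimates ---------------------------------------

def published_calibration() -> pd.DataFrame:
    """Published best-estimate scaling parameters and posterior standard
    deviations per major group (H, F, I), indexed by major_group.

    Parameter order: k_corn, k_wheat, k_aoc, k_seu, k_ceu, k_neu, alpha.
    """
    df = pd.read_csv(_data_path("published_calibration.csv"))
    return df.set_index("major_group")
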