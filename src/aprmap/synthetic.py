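"""Synthetic input generation with known ground truth.

Every input the pipeline consumes at continental scale has a desk-scale
synthetic counterpart here: a fine categorical crop raster and a
co-registered land-cover raster (with planted disagreement patches that
exercise each fusion rule), a country-partition raster of contiguous
blocks, coarse positive application-rate grids in geographic coordinates
(so the nearest-neighbour projection crosses a real CRS boundary), and
usage records generated forward through the scaling model with known
parameters, multiplicative decadic-log noise and configurable sparsity.

Defaults emulate the study conditions: 10 m fine cells upscaled by 25 to
250 m, the full shipped country list, crop-class frequencies echoing the
published surface-area shares, reference records at chemical-class/year
granularity over 2015-2020, and factor-two log-normal scatter
(``noise_sd_log10 = 0.3``) with 15 % of (crop, country) keys unreported.
All outputs are deterministic functions of the scenario seed.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration_prep import CORN_LABELS, WHEAT_LABELS
from .domain import (
    PesticideTaxonomy,
    RegionAssignment,
    load_regions,
    load_taxonomy,
)
from .geo import Affine, from_origin, laea_inverse
from .model import PARAM_NAMES, ScalingParameters, scaled_mass
from .raster import Raster

__all__ = ["SyntheticScenario", "gen_crop_raster", "gen_coarse_apr",
           "gen_reference_masses", "gen_authorizations", "generate_bundle"]

#: Fine crop-map class frequencies echoing the published surface-area shares,
#: plus woodland/shrubland (300) and grasslands (500) pools for the fusion rules.
DEFAULT_CLASS_PROBABILITIES: dict[int, float] = {
    211: 0.200, 212: 0.012, 213: 0.076, 214: 0.012, 216: 0.150, 217: 0.005,
    221: 0.006, 222: 0.012, 231: 0.032, 232: 0.050, 233: 0.004, 240: 0.012,
    290: 0.031, 350: 0.062, 510: 0.160, 300: 0.080, 500: 0.096,
}

DEFAULT_TRUTH: dict[str, ScalingParameters] = {
    "H": ScalingParameters(0.7, 1.8, 2.5, 1.1, 1.2, 2.0, 0.92),
    "F": ScalingParameters(0.6, 3.0, 2.0, 0.9, 1.4, 1.3, 0.99),
    "I": ScalingParameters(1.6, 0.8, 1.9, 0.85, 1.15, 0.9, 1.05),
}

#: Ingredients covering all three major groups and all calibration crops.
DEFAULT_AI_LIST = (
    "Glyphosate", "Pendimethalin",          # H
    "Mancozeb", "Azoxystrobin",             # F
    "Chlorpyrifos", "Dimethoate",           # I
)

_AOC_LABELS = ("Soybeans", "Potatoes")


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study.

    ``grid_shape`` is the fine raster size; countries are contiguous
    column-blocks aligned with the upscaled grid. ``apr_mean``/``apr_cv``
    set the log-normal coarse rate field (a per-ingredient dict may override
    the mean). ``extra_class_fraction`` adds usage mass in chemical classes
    outside the taxonomy so coverage fractions are below one.
    """

    seed: int = 0
    grid_shape: tuple[int, int] = (1875, 2700)
    upscale_factor: int = 25
    cell_size_fine: float = 10.0
    n_countries: int = 27
    class_probabilities: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBABILITIES)
    )
    ai_list: tuple[str, ...] = DEFAULT_AI_LIST
    apr_mean: float = 1.2          # kg/ha
    apr_cv: float = 0.4
    apr_mean_by_ai: dict[str, float] = field(default_factory=dict)
    coarse_shape: tuple[int, int] = (8, 8)
    truth_params: dict[str, ScalingParameters] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH)
    )
    speckle_fraction: float = 0.1
    noise_sd_log10: float = 0.3
    sparsity: float = 0.15
    extra_class_fraction: float = 0.25
    years: tuple[int, ...] = (2015, 2016, 2017, 2018, 2019, 2020)
    origin: tuple[float, float] = (4321000.0, 3210000.0)
    crs: str = "EPSG:3035"

    def __post_init__(self) -> None:
        total = sum(self.class_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities sum to {total}, not 1")
        if self.upscale_factor < 1:
            raise ValueError("upscale_factor must be >= 1")
        if self.noise_sd_log10 < 0:
            raise ValueError("noise_sd_log10 must be nonnegative")
        if not (0 <= self.sparsity < 1):
            raise ValueError("sparsity must be in [0, 1)")
        if self.n_countries < 1:
            raise ValueError("need at least one country")

    @classmethod
    def small(cls, seed: int = 0, **kw) -> "SyntheticScenario":
        """Fast four-country fixture (50 m cells upscaled by 5 to 250 m).

        Noise is moderate and no keys are dropped: with only 12 reference
        keys per major group against 7 parameters, the small fixture cannot
        afford sparsity without losing identifiability.
        """
        defaults = dict(
            seed=seed,
            grid_shape=(150, 150),
            upscale_factor=5,
            cell_size_fine=50.0,
            n_countries=4,
            coarse_shape=(6, 6),
            apr_mean=2.5,
            noise_sd_log10=0.2,
            sparsity=0.0,
        )
        defaults.update(kw)
        return cls(**defaults)

    @property
    def transform(self) -> Affine:
        return from_origin(self.origin[0], self.origin[1],
                           self.cell_size_fine, self.cell_size_fine)

    def country_names(self, regions: RegionAssignment | None = None) -> dict[int, str]:
        """Country id -> name, interleaving the three regions so every
        region is populated once n_countries >= 3."""
        if regions is None:
            regions = load_regions()
        by_region: dict[str, list[str]] = {"SEU": [], "CEU": [], "NEU": []}
        for country in regions.countries:
            by_region[regions.region(country)].append(country)
        ordered: list[str] = []
        i = 0
        while len(ordered) < self.n_countries:
            region = ("SEU", "CEU", "NEU")[i % 3]
            pool = by_region[region]
            if pool:
                ordered.append(pool.pop(0))
            elif not any(by_region.values()):
                raise ValueError("n_countries exceeds the available country list")
            i += 1
        return {i + 1: name for i, name in enumerate(ordered)}

    def taxonomy(self) -> PesticideTaxonomy:
        return load_taxonomy().subset(self.ai_list)


def _country_strips(s: SyntheticScenario) -> np.ndarray:
    """Country-id raster (fine grid): contiguous column blocks aligned with
    the upscaled grid so the partition survives modal upscaling exactly.

    Strip widths follow a geometric size progression (largest country several
    times wider than the smallest, echoing the spread of national cropland
    areas); without that spread the first-guess masses barely vary between
    countries and the scaling exponent is poorly identified. A minimum strip
    width keeps even the smallest country's masses above the reference
    retention threshold at desk scale.
    """
    nrows, ncols = s.grid_shape
    factor = s.upscale_factor
    out_cols = -(-ncols // factor)
    n = s.n_countries
    if out_cols < n:
        raise ValueError(
            f"grid too narrow: {out_cols} upscaled columns for {n} countries"
        )
    min_width = max(1, min(3, out_cols // n))
    weights = np.logspace(0.0, 0.8, n)
    widths = np.maximum(
        min_width, np.floor(weights / weights.sum() * out_cols).astype(int)
    )
    widths[np.argmax(widths)] += out_cols - widths.sum()  # absorb rounding
    if widths.min() < 1:
        raise ValueError("degenerate country partition (zero-area country)")
    block_ids = np.repeat(np.arange(n), widths)
    fine_ids = np.repeat(block_ids, factor)[:ncols]
    return np.broadcast_to(fine_ids + 1, (nrows, ncols)).copy()


def gen_crop_raster(s: SyntheticScenario) -> tuple[Raster, Raster, Raster]:
    """Fine crop raster, co-registered land-cover raster, country raster.

    The land-cover raster agrees with the crop raster (rice, orchard and
    pasture classes carry their land-cover codes; everything else a neutral
    arable code) except for planted disagreement patches that trigger each
    of the three correction rules.
    """
    rng = np.random.default_rng(s.seed)
    nrows, ncols = s.grid_shape
    codes = np.array(sorted(s.class_probabilities), dtype=np.int32)
    probs = np.array([s.class_probabilities[c] for c in codes])

    # field-structured draw: one class per upscaled block plus pixel speckle,
    # so the per-pixel marginal is exactly the class distribution while the
    # block mode (what modal upscaling extracts) matches the block class
    f = s.upscale_factor
    out_r, out_c = -(-nrows // f), -(-ncols // f)
    blocks = rng.choice(codes, size=(out_r, out_c), p=probs)
    eucm = np.repeat(np.repeat(blocks, f, axis=0), f, axis=1)[:nrows, :ncols]
    eucm = np.ascontiguousarray(eucm).astype(np.int32)
    if s.speckle_fraction > 0:
        speckle = rng.random((nrows, ncols)) < s.speckle_fraction
        eucm[speckle] = rng.choice(codes, size=int(speckle.sum()), p=probs)

    # land cover consistent with the crop map by default
    corine = np.full((nrows, ncols), 200, dtype=np.int32)  # neutral arable
    corine[eucm == 217] = 213
    corine[eucm == 350] = 221
    corine[eucm == 510] = 231

    # rule 1: a rice patch only visible in the land cover
    ph, pw = max(2, nrows // 20), max(2, ncols // 20)
    r0 = int(rng.integers(0, nrows - ph))
    c0 = int(rng.integers(0, ncols - pw))
    corine[r0 : r0 + ph, c0 : c0 + pw] = 213
    # rule 2: woodland/shrubland pixels revealed as permanent crops
    wood = (eucm == 300) & (rng.random((nrows, ncols)) < 0.5)
    corine[wood] = rng.choice([221, 222, 223], size=int(wood.sum()))
    # rule 3: grasslands revealed as pastures
    grass = (eucm == 500) & (rng.random((nrows, ncols)) < 0.5)
    corine[grass] = 231

    transform = s.transform
    countries = _country_strips(s)
    ids = np.unique(countries)
    if len(ids) != s.n_countries:
        raise ValueError("degenerate country partition (zero-area country)")
    return (
        Raster(eucm, transform, s.crs, nodata=None),
        Raster(corine, transform, s.crs, nodata=None),
        Raster(countries.astype(np.int32), transform, s.crs, nodata=0),
    )


def gen_coarse_apr(s: SyntheticScenario, ai_name: str) -> Raster:
    """Coarse application-rate grid for one ingredient, in geographic
    coordinates covering the fine extent (log-normal around the mean)."""
    mean = float(s.apr_mean_by_ai.get(ai_name, s.apr_mean))
    if mean <= 0:
        raise ValueError("apr_mean must be positive")
    cv = float(s.apr_cv)
    rng = np.random.default_rng(
        np.random.SeedSequence([s.seed, zlib.crc32(ai_name.encode("utf-8"))])
    )

    nrows, ncols = s.grid_shape
    t = s.transform
    xs = [t.c, t.c + ncols * t.a]
    ys = [t.f, t.f + nrows * t.e]
    corner_x, corner_y = np.meshgrid(xs, ys)
    lon, lat = laea_inverse(corner_x.ravel(), corner_y.ravel())
    pad_lon = 0.05 * (lon.max() - lon.min() + 1e-9) + 1e-6
    pad_lat = 0.05 * (lat.max() - lat.min() + 1e-9) + 1e-6
    west, east = lon.min() - pad_lon, lon.max() + pad_lon
    south, north = lat.min() - pad_lat, lat.max() + pad_lat

    crows, ccols = s.coarse_shape
    transform = from_origin(west, north, (east - west) / ccols, (north - south) / crows)
    if cv == 0:
        values = np.full((crows, ccols), mean)
    else:
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean) - sigma2 / 2.0
        values = rng.lognormal(mu, np.sqrt(sigma2), size=(crows, ccols))
    return Raster(values, transform, "EPSG:4326", nodata=-9999.0)


def gen_authorizations(
    s: SyntheticScenario,
    banned: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Explicit authorization table for every (ingredient, country) pair;
    ``banned`` maps ingredient -> list of countries where it is banned."""
    banned = banned or {}
    names = list(s.country_names().values())
    rows = []
    for ai in s.ai_list:
        for country in names:
            rows.append((ai, country, 0 if country in banned.get(ai, []) else 1))
    return pd.DataFrame(rows, columns=["ai_name", "country", "approved"])


def gen_reference_masses(
    s: SyntheticScenario,
    first_guess: pd.DataFrame,
    regions: RegionAssignment | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Usage records from the forward scaling model, plus ground truth.

    For each first-guess key (major group, crop, country) a target mass
    m* = k_C k_L m~^alpha 10^eps is drawn (eps ~ N(0, noise_sd_log10)) and
    whole keys are dropped at the sparsity rate. The target is then
    disaggregated into equal shares over the taxonomy's chemical classes of
    the group, split over two crop labels, and repeated for every year in
    the window, mirroring the granularity of real usage statistics. Extra
    mass in an unmapped chemical class (``<mg>88_88``) makes totals exceed
    the selectable mass.

    Returns ``(records, totals, truth_table)``: the record table consumed by
    the preparation stage, the full major-group totals for coverage
    fractions, and the exact per-key target masses before disaggregation.
    """
    if regions is None:
        regions = load_regions()
    rng = np.random.default_rng(np.random.SeedSequence([s.seed, 7]))
    tax = s.taxonomy()
    classes_by_group: dict[str, list[str]] = {}
    for r in tax.records:
        classes_by_group.setdefault(r.major_group, [])
        if r.chem_class_code not in classes_by_group[r.major_group]:
            classes_by_group[r.major_group].append(r.chem_class_code)

    crop_labels = {
        "Corn": [(lbl, 1 / len(CORN_LABELS)) for lbl in sorted(CORN_LABELS)],
        "Wheat": [("Durum wheat", 0.5), ("Common wheat and spelt", 0.5)],
        "AOC": [(lbl, 1 / len(_AOC_LABELS)) for lbl in _AOC_LABELS],
    }

    records, totals, truth_rows = [], [], []
    for row in first_guess.itertuples():
        mg = row.major_group
        if mg not in s.truth_params:
            raise ValueError(f"no truth parameters for major group {mg!r}")
        if row.mass_kg <= 0:
            continue
        target = scaled_mass(
            s.truth_params[mg], row.crop, row.country, row.mass_kg, regions
        )
        if s.noise_sd_log10 > 0:
            target *= 10.0 ** rng.normal(0.0, s.noise_sd_log10)
        dropped = rng.random() < s.sparsity
        extra = s.extra_class_fraction * target
        totals.append((mg, row.crop, row.country, target + extra))
        truth_rows.append((mg, row.crop, row.country, target, dropped))
        if dropped:
            continue
        group_classes = classes_by_group[mg]
        share = target / len(group_classes)
        for code in group_classes:
            for label, w in crop_labels[row.crop]:
                for year in s.years:
                    records.append((row.country, label, code, year, share * w))
        # unmapped-class mass: selectable fraction stays below one
        if extra > 0:
            for label, w in crop_labels[row.crop]:
                for year in s.years:
                    records.append((row.country, label, f"{mg}88_88", year, extra * w))

    records_df = pd.DataFrame(
        records, columns=["country", "crop_label", "chem_class_code", "year", "mass_kg"]
    )
    totals_df = pd.DataFrame(
        totals, columns=["major_group", "crop", "country", "mass_kg"]
    ).sort_values(["major_group", "crop", "country"], ignore_index=True)
    truth_df = pd.DataFrame(
        truth_rows, columns=["major_group", "crop", "country", "m_star_true", "dropped"]
    ).sort_values(["major_group", "crop", "country"], ignore_index=True)
    return records_df, totals_df, truth_df


def generate_bundle(s: SyntheticScenario, out_dir: str | Path) -> dict:
    """Write a self-contained input fixture directory plus ground truth.

    Produces the crop/land-cover/country GeoTIFFs, one coarse rate GeoTIFF
    per ingredient, the authorization and region CSVs, the usage-record CSV
    and a ``truth.json`` with the generating parameters. Returns the
    manifest dictionary.
    """
    from .raster import write_raster  # local to keep import graph flat
    from . import pipeline

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eucm, corine, countries = gen_crop_raster(s)
    write_raster(eucm, out / "eucm.tif")
    write_raster(corine, out / "corine.tif")
    write_raster(countries, out / "countries.tif")
    for ai in s.ai_list:
        write_raster(gen_coarse_apr(s, ai), out / f"apr_{ai.replace(' ', '-')}.tif")
    gen_authorizations(s).to_csv(out / "authorizations.csv", index=False)

    regions = load_regions()
    names = s.country_names(regions)
    regions.to_frame()[regions.to_frame()["country"].isin(names.values())].to_csv(
        out / "regions.csv", index=False
    )
    pd.DataFrame(
        sorted(names.items()), columns=["id", "country"]
    ).to_csv(out / "country_ids.csv", index=False)

    stage = pipeline.fuse_and_project(s, eucm, corine, countries)
    records, totals, truth = gen_reference_masses(s, stage.first_guess, regions)
    records.to_csv(out / "reference_records.csv", index=False)
    totals.to_csv(out / "group_totals.csv", index=False)

    config = {
        "eucm": str(out / "eucm.tif"),
        "corine": str(out / "corine.tif"),
        "countries": str(out / "countries.tif"),
        "country_ids": str(out / "country_ids.csv"),
        "apr_grids": {
            ai: str(out / f"apr_{ai.replace(' ', '-')}.tif") for ai in s.ai_list
        },
        "authorizations": str(out / "authorizations.csv"),
        "reference_records": str(out / "reference_records.csv"),
        "group_totals": str(out / "group_totals.csv"),
        "out_dir": str(out / "products"),
        "upscale_factor": s.upscale_factor,
        "mc_seed": s.seed,
        "years": list(s.years),
    }
    import yaml

    (out / "config.yaml").write_text(yaml.safe_dump(config))

    truth_payload = {
        "seed": s.seed,
        "scenario": {
            k: v for k, v in dataclasses.asdict(s).items()
            if k not in ("truth_params", "class_probabilities")
        },
        "class_probabilities": {str(k): v for k, v in s.class_probabilities.items()},
        "truth_params": {
            mg: dict(zip(PARAM_NAMES, p.as_array().tolist()))
            for mg, p in s.truth_params.items()
        },
        "country_ids": {str(k): v for k, v in names.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth_payload, indent=2))
    return truth_payload
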