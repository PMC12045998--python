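"""Pipeline orchestration: stage wiring, configuration and manifests.

The full procedure runs seven stages in order: crop-map fusion, rate
projection and first-guess mass, reference preparation, calibration,
Monte-Carlo propagation, scenario-map generation, and quality indexing.
:func:`run_synthetic` executes everything in memory from a
:class:`~aprmap.synthetic.SyntheticScenario`; :func:`run_pipeline` is the
file-based equivalent driven by a :class:`PipelineConfig` (YAML), writing
every intermediate product and a manifest so stages are resumable and
outputs reproducible from config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import montecarlo
from .calibration_prep import (
    DEFAULT_THRESHOLD_KG,
    coverage_fractions,
    prepare_reference,
)
from .domain import (
    AuthorizationTable,
    RegionAssignment,
    load_authorizations,
    load_crop_class_map,
    load_regions,
    load_taxonomy,
)
from .fusion import aggregate_labels, apply_corine_corrections, modal_upscale
from .mapping import SCENARIOS, apply_correction, correction_factors, write_scenario_maps
from .model import CalibrationResults, ScalingModel
from .projection import apply_authorization, first_guess_mass, project_apr
from .quality import qi_raster, qi_table, qi_with_fallback, validation_ratio
from .raster import Raster, read_raster, write_raster

logger = logging.getLogger("aprmap.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "run_synthetic", "fuse_and_project", "StageOutputs"]


@dataclass
class StageOutputs:
    """Products of the fusion + projection stages (in-memory form)."""

    crops: Raster                      # class-coded 250 m raster
    countries: Raster                  # country-id 250 m raster
    country_names: dict[int, str]
    fine_apr: dict[str, Raster]        # per-ingredient first-guess rates
    first_guess: pd.DataFrame          # m~ per (major group, crop, country)


def fuse_and_project(scenario, eucm, corine, countries, auth: AuthorizationTable | None = None) -> StageOutputs:
    """Stages 1-2 on synthetic inputs: fuse, upscale, aggregate, project,
    authorize and accumulate the first-guess mass."""
    from .synthetic import gen_authorizations, gen_coarse_apr

    class_map = load_crop_class_map()
    tax = scenario.taxonomy()
    names = scenario.country_names()

    corrected = apply_corine_corrections(eucm, corine)
    upscaled = modal_upscale(corrected, scenario.upscale_factor)
    crops = aggregate_labels(upscaled, class_map)
    countries_up = modal_upscale(countries, scenario.upscale_factor)

    if auth is None:
        auth_df = gen_authorizations(scenario)
        auth = AuthorizationTable(
            {(r.ai_name, r.country): bool(r.approved) for r in auth_df.itertuples()}
        )

    fine_apr = {}
    for ai in scenario.ai_list:
        coarse = gen_coarse_apr(scenario, ai)
        fine = project_apr(coarse, crops)
        fine_apr[ai] = apply_authorization(fine, ai, auth, countries_up, names)

    first_guess = first_guess_mass(fine_apr, crops, countries_up, names, tax)
    return StageOutputs(crops, countries_up, names, fine_apr, first_guess)


def run_synthetic(
    scenario,
    n_realizations: int = montecarlo.DEFAULT_N_REALIZATIONS,
    mc_seed: int | None = None,
    threshold_kg: float = DEFAULT_THRESHOLD_KG,
    make_rasters: bool = True,
) -> dict:
    """End-to-end run on a synthetic scenario; returns all stage products.

    The returned dict holds the stage outputs, the prepared reference table,
    per-group fit results, scenario masses, correction factors, scenario and
    QI rasters, validation ratios and the generator's ground truth.
    """
    from .synthetic import gen_crop_raster, gen_reference_masses

    regions = load_regions()
    tax = scenario.taxonomy()
    mc_seed = scenario.seed if mc_seed is None else mc_seed

    eucm, corine, countries = gen_crop_raster(scenario)
    stage = fuse_and_project(scenario, eucm, corine, countries)

    records, totals, truth = gen_reference_masses(scenario, stage.first_guess, regions)
    m_star = prepare_reference(records, tax, window=scenario.years, threshold_kg=threshold_kg)
    coverage, coverage_agg = coverage_fractions(m_star, totals)

    results: dict[str, CalibrationResults] = {}
    scenario_masses = []
    for mg in sorted(m_star["major_group"].unique()):
        model = ScalingModel(m_star, stage.first_guess, regions, major_group=mg)
        res = model.fit()
        results[mg] = res
        mt_mg = stage.first_guess[stage.first_guess["major_group"] == mg]
        scen = res.simulate_scenarios(mt_mg, n=n_realizations, seed=mc_seed)
        scenario_masses.append(scen)
    scenario_mass = pd.concat(scenario_masses, ignore_index=True)

    K = correction_factors(scenario_mass, stage.first_guess)

    scenario_rasters = {}
    qi_rasters = {}
    fitted = pd.concat([r.fittedvalues for r in results.values()], ignore_index=True)
    direct_qi = qi_table(fitted, m_star)
    qi = qi_with_fallback(direct_qi, stage.first_guess, regions)
    ratios = validation_ratio(scenario_mass, m_star)

    if make_rasters:
        for ai in scenario.ai_list:
            mg = tax.major_group_of(ai)
            if mg not in results:
                continue
            for s_name in SCENARIOS:
                scenario_rasters[(ai, s_name)] = apply_correction(
                    stage.fine_apr[ai], ai, s_name, K,
                    stage.crops, stage.countries, stage.country_names, tax, regions,
                )
            qi_rasters[ai] = qi_raster(
                qi, stage.crops, stage.countries, stage.country_names, tax, ai
            )

    return {
        "stage": stage,
        "records": records,
        "totals": totals,
        "truth": truth,
        "m_star": m_star,
        "coverage": coverage,
        "coverage_aggregates": coverage_agg,
        "results": results,
        "scenario_mass": scenario_mass,
        "correction_factors": K,
        "scenario_rasters": scenario_rasters,
        "qi": qi,
        "qi_rasters": qi_rasters,
        "validation_ratios": ratios,
    }


# --- file-based pipeline ----------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths and knobs of a file-based run; see ``PipelineConfig.from_yaml``."""

    eucm: str
    corine: str
    countries: str
    country_ids: str          # CSV: id, country
    apr_grids: dict[str, str]  # ingredient -> coarse GeoTIFF
    authorizations: str
    reference_records: str
    out_dir: str
    group_totals: str | None = None
    regions: str | None = None
    taxonomy: str | None = None
    crop_classes: str | None = None
    upscale_factor: int = 25
    threshold_kg: float = DEFAULT_THRESHOLD_KG
    mc_n: int = montecarlo.DEFAULT_N_REALIZATIONS
    mc_seed: int = 0
    years: tuple[int, ...] = (2015, 2016, 2017, 2018, 2019, 2020)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def validate(self) -> None:
        missing = [
            p for p in [
                self.eucm, self.corine, self.countries, self.country_ids,
                self.authorizations, self.reference_records,
                *self.apr_grids.values(),
            ]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _load_country_names(path: str | Path) -> dict[int, str]:
    df = pd.read_csv(path)
    if not {"id", "country"}.issubset(df.columns):
        raise ValueError("country ids file needs columns id, country")
    return {int(r.id): str(r.country) for r in df.itertuples()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages from files, writing products and a manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "mc_seed": config.mc_seed, "mc_n": config.mc_n}

    regions = load_regions(config.regions)
    tax = load_taxonomy(config.taxonomy)
    tax = tax.subset([ai for ai in config.apr_grids if ai in tax.ai_names]) if config.apr_grids else tax
    class_map = load_crop_class_map(config.crop_classes)
    auth = load_authorizations(config.authorizations)
    names = _load_country_names(config.country_ids)

    # stage 1: fusion
    eucm = read_raster(config.eucm)
    corine = read_raster(config.corine)
    corrected = apply_corine_corrections(eucm, corine)
    crops = aggregate_labels(modal_upscale(corrected, config.upscale_factor), class_map)
    countries = modal_upscale(read_raster(config.countries), config.upscale_factor)
    write_raster(crops, out / "crops_250.tif")
    write_raster(countries, out / "countries_250.tif")
    manifest["stages"].append({"name": "fuse", "shape": list(crops.shape)})

    # stage 2: projection + first-guess mass
    fine_apr = {}
    for ai, path in config.apr_grids.items():
        fine = project_apr(read_raster(path), crops)
        fine_apr[ai] = apply_authorization(fine, ai, auth, countries, names)
    m_tilde = first_guess_mass(fine_apr, crops, countries, names, tax)
    m_tilde.to_csv(out / "first_guess_mass.csv", index=False)
    manifest["stages"].append({"name": "project", "n_keys": len(m_tilde)})

    # stage 3: reference preparation
    records = pd.read_csv(config.reference_records)
    m_star = prepare_reference(records, tax, window=config.years, threshold_kg=config.threshold_kg)
    m_star.to_csv(out / "reference_mass.csv", index=False)
    if config.group_totals:
        totals = pd.read_csv(config.group_totals)
        coverage, agg = coverage_fractions(m_star, totals)
        coverage.to_csv(out / "coverage.csv", index=False)
        agg.rename("coverage").to_csv(out / "coverage_aggregates.csv")
    manifest["stages"].append({"name": "prepare", "n_reference": len(m_star)})

    # stage 4: calibration
    results = {}
    fitted_parts = []
    for mg in sorted(m_star["major_group"].unique()):
        res = ScalingModel(m_star, m_tilde, regions, major_group=mg).fit()
        results[mg] = res
        (out / f"calibration_{mg}.json").write_text(json.dumps(res.to_dict(), indent=2))
        fitted_parts.append(res.fittedvalues)
    pd.concat(fitted_parts, ignore_index=True).to_csv(out / "fitted_mass.csv", index=False)
    manifest["stages"].append({"name": "calibrate", "groups": sorted(results)})

    # stage 5: Monte-Carlo propagation
    scen_parts = []
    for mg, res in results.items():
        mt_mg = m_tilde[m_tilde["major_group"] == mg]
        scen_parts.append(res.simulate_scenarios(mt_mg, n=config.mc_n, seed=config.mc_seed))
    scenario_mass = pd.concat(scen_parts, ignore_index=True)
    scenario_mass.to_csv(out / "scenario_mass.csv", index=False)
    manifest["stages"].append({"name": "propagate", "n_keys": len(scenario_mass)})

    # stage 6: scenario maps
    K = correction_factors(scenario_mass, m_tilde)
    K.to_csv(out / "correction_factors.csv", index=False)
    grids = {}
    for ai in fine_apr:
        mg = tax.major_group_of(ai)
        if mg not in results:
            logger.warning("no calibration for %s (group %s); skipped", ai, mg)
            continue
        for s_name in SCENARIOS:
            grids[(ai, s_name)] = apply_correction(
                fine_apr[ai], ai, s_name, K, crops, countries, names, tax, regions
            )
    files = write_scenario_maps(grids, out / "maps", manifest_extra={"mc_seed": config.mc_seed})
    manifest["stages"].append({"name": "maps", "n_files": len(files)})

    # stage 7: quality index + validation
    fitted = pd.concat([r.fittedvalues for r in results.values()], ignore_index=True)
    qi = qi_with_fallback(qi_table(fitted, m_star), m_tilde, regions)
    qi.to_csv(out / "qi.csv", index=False)
    for mg in results:
        ai = next(a for a in fine_apr if tax.major_group_of(a) == mg)
        write_raster(
            qi_raster(qi, crops, countries, names, tax, ai), out / f"QI_{mg}.tif"
        )
    ratios = validation_ratio(scenario_mass, m_star)
    ratios.to_csv(out / "validation_ratio.csv", index=False)
    manifest["stages"].append({"name": "quality", "n_qi": len(qi)})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
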