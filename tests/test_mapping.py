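"""Correction factors, scenario rasters, mass closure, map output."""

import json

import numpy as np
import pandas as pd
import pytest

from aprmap.domain import PCG_CODES, pcg_class_of_code, to_calibration_crop
from aprmap.geo import from_origin
from aprmap.mapping import (
    SCENARIOS,
    apply_correction,
    correction_factors,
    write_scenario_maps,
)
from aprmap.raster import Raster, read_raster


def _scenario_table(rows):
    return pd.DataFrame(
        rows,
        columns=["major_group", "crop", "country", "mass_kg", "m_low", "m_median", "m_high"],
    )


class TestCorrectionFactors:
    def test_equal_masses_give_unity(self):
        scen = _scenario_table([("H", "Corn", "Italy", 100.0, 100.0, 100.0, 100.0)])
        m_tilde = scen[["major_group", "crop", "country", "mass_kg"]]
        K = correction_factors(scen, m_tilde)
        np.testing.assert_allclose(K["K"], 1.0)

    def test_doubled_mass_gives_two(self):
        scen = _scenario_table([("H", "Corn", "Italy", 100.0, 150.0, 200.0, 300.0)])
        m_tilde = scen[["major_group", "crop", "country", "mass_kg"]]
        K = correction_factors(scen, m_tilde).set_index("scenario")["K"]
        assert K["Low"] == pytest.approx(1.5)
        assert K["Median"] == pytest.approx(2.0)
        assert K["High"] == pytest.approx(3.0)

    def test_matches_elementwise_ratio_oracle(self, small_noisy_run):
        _, out = small_noisy_run
        scen = out["scenario_mass"]
        m_tilde = out["stage"].first_guess
        K = correction_factors(scen, m_tilde)
        merged = K.merge(m_tilde, on=["major_group", "crop", "country"])
        col = {"Low": "m_low", "Median": "m_median", "High": "m_high"}
        for row in merged.itertuples():
            scen_mass = scen.set_index(["major_group", "crop", "country"]).loc[
                (row.major_group, row.crop, row.country), col[row.scenario]
            ]
            assert row.K == pytest.approx(scen_mass / row.mass_kg, rel=1e-12)

    def test_ordering_per_key(self, small_noisy_run):
        _, out = small_noisy_run
        K = out["correction_factors"].pivot_table(
            index=["major_group", "crop", "country"], columns="scenario", values="K"
        )
        assert (K["Low"] <= K["Median"]).all() and (K["Median"] <= K["High"]).all()

    def test_zero_first_guess_with_mass_rejected(self):
        scen = _scenario_table([("H", "Corn", "Italy", 0.0, 1.0, 2.0, 3.0)])
        m_tilde = scen[["major_group", "crop", "country", "mass_kg"]]
        with pytest.raises(ValueError, match="Italy"):
            correction_factors(scen, m_tilde)


class TestApplyCorrection:
    def _setup(self, taxonomy):
        t = from_origin(0, 0, 250, 250)
        crops = Raster(
            np.array([[PCG_CODES["Corn"]] * 4, [PCG_CODES["Wheat"]] * 4] * 2, dtype=np.int32),
            t, "EPSG:3035", nodata=0,
        )
        countries = Raster(
            np.repeat([[1, 1, 2, 2]], 4, axis=0).astype(np.int32), t, "EPSG:3035", nodata=0
        )
        apr = Raster(np.full((4, 4), 2.0), t, "EPSG:3035", nodata=-9999.0)
        names = {1: "Italy", 2: "Germany"}
        return apr, crops, countries, names

    def _unit_K(self, value_by_country=None):
        rows = []
        for crop in ("Corn", "Wheat", "AOC"):
            for country in ("Italy", "Germany"):
                for s in SCENARIOS:
                    v = (value_by_country or {}).get(country, 1.0)
                    rows.append(("H", crop, country, s, v))
        return pd.DataFrame(rows, columns=["major_group", "crop", "country", "scenario", "K"])

    def test_unit_factor_is_identity_on_applicable_pixels(self, taxonomy, regions):
        apr, crops, countries, names = self._setup(taxonomy)
        out = apply_correction(
            apr, "Glyphosate", "Median", self._unit_K(), crops, countries, names, taxonomy, regions
        )
        valid = out.values != out.nodata
        np.testing.assert_allclose(out.values[valid], apr.values[valid])

    def test_country_specific_doubling(self, taxonomy, regions):
        apr, crops, countries, names = self._setup(taxonomy)
        K = self._unit_K({"Italy": 2.0, "Germany": 1.0})
        out = apply_correction(
            apr, "Glyphosate", "Median", K, crops, countries, names, taxonomy, regions
        )
        italy = countries.values == 1
        valid = out.values != out.nodata
        np.testing.assert_allclose(out.values[italy & valid], 4.0)
        np.testing.assert_allclose(out.values[~italy & valid], 2.0)

    def test_non_applicable_crops_are_nodata(self, taxonomy, regions):
        # Mesotrione applies to corn only: wheat pixels must carry nodata
        apr, crops, countries, names = self._setup(taxonomy)
        out = apply_correction(
            apr, "Mesotrione", "Median", self._unit_K(), crops, countries, names, taxonomy, regions
        )
        wheat = crops.values == PCG_CODES["Wheat"]
        assert (out.values[wheat] == out.nodata).all()
        assert (out.values[~wheat] != out.nodata).all()

    def test_missing_key_falls_back_to_region_average(self, taxonomy, regions):
        # Spain lacks direct factors; same-region (SEU) Italy donates its K
        apr, crops, countries, names = self._setup(taxonomy)
        names = {1: "Italy", 2: "Spain"}
        rows = []
        for crop in ("Corn", "Wheat", "AOC"):
            for s in SCENARIOS:
                rows.append(("H", crop, "Italy", s, 2.0))
        K = pd.DataFrame(rows, columns=["major_group", "crop", "country", "scenario", "K"])
        out = apply_correction(
            apr, "Glyphosate", "Median", K, crops, countries, names, taxonomy, regions
        )
        spain = countries.values == 2
        valid = out.values != out.nodata
        np.testing.assert_allclose(out.values[spain & valid], 4.0)

    def test_fallback_error_when_no_donors(self, taxonomy, regions):
        apr, crops, countries, names = self._setup(taxonomy)
        K = self._unit_K()
        K = K[K["crop"] != "Corn"]  # no Corn factors anywhere
        with pytest.raises(KeyError, match="Corn"):
            apply_correction(
                apr, "Glyphosate", "Median", K, crops, countries, names, taxonomy, regions
            )


class TestMassClosure:
    def test_scenario_rasters_conserve_scenario_mass(self, small_zero_noise_run, taxonomy):
        scenario, out = small_zero_noise_run
        stage = out["stage"]
        scen = out["scenario_mass"].set_index(["major_group", "crop", "country"])
        tax = scenario.taxonomy()
        col = {"Low": "m_low", "Median": "m_median", "High": "m_high"}
        area = stage.crops.cell_area_ha

        sums: dict = {}
        for (ai, s_name), grid in out["scenario_rasters"].items():
            mg = tax.major_group_of(ai)
            valid = grid.values != grid.nodata
            for cid, cname in stage.country_names.items():
                sel_c = valid & (stage.countries.values == cid)
                for code in np.unique(stage.crops.values[sel_c]):
                    crop = to_calibration_crop(pcg_class_of_code(int(code)))
                    key = (mg, crop, cname, s_name)
                    sel = sel_c & (stage.crops.values == code)
                    sums[key] = sums.get(key, 0.0) + float(grid.values[sel].sum()) * area

        assert sums, "no scenario rasters produced"
        for (mg, crop, cname, s_name), total in sums.items():
            expected = scen.loc[(mg, crop, cname), col[s_name]]
            assert total == pytest.approx(expected, rel=1e-6), (mg, crop, cname, s_name)

    def test_scenarios_monotone_pixelwise(self, small_noisy_run):
        _, out = small_noisy_run
        by_ai: dict = {}
        for (ai, s_name), grid in out["scenario_rasters"].items():
            by_ai.setdefault(ai, {})[s_name] = grid
        for ai, grids in by_ai.items():
            low, med, high = grids["Low"], grids["Median"], grids["High"]
            valid = low.values != low.nodata
            assert (low.values[valid] <= med.values[valid] + 1e-9).all()
            assert (med.values[valid] <= high.values[valid] + 1e-9).all()

    def test_excluded_pixels_are_nodata(self, small_noisy_run):
        _, out = small_noisy_run
        stage = out["stage"]
        excluded = stage.crops.values == stage.crops.nodata
        for grid in out["scenario_rasters"].values():
            assert (grid.values[excluded] == grid.nodata).all()


class TestWriteScenarioMaps:
    def test_file_set_and_roundtrip(self, tmp_path):
        t = from_origin(4321000, 3210000, 250, 250)
        rng = np.random.default_rng(0)
        grids = {
            (ai, s): Raster(rng.random((5, 5)).astype(np.float32), t, "EPSG:3035", nodata=-9999.0)
            for ai in ("Glyphosate", "Mancozeb")
            for s in SCENARIOS
        }
        files = write_scenario_maps(grids, tmp_path, manifest_extra={"mc_seed": 1})
        assert len(files) == 6
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["mc_seed"] == 1 and len(manifest["files"]) == 6
        back = read_raster(tmp_path / "Glyphosate_Median.tif")
        np.testing.assert_array_equal(
            back.values, grids[("Glyphosate", "Median")].values
        )
        np.testing.assert_allclose(back.transform, t)
        assert back.crs == "EPSG:3035"
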