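"""Scaling-model evaluation, objective, fitting and posterior uncertainty."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aprmap.domain import CALIBRATION_CROPS, REGIONS, published_calibration
from aprmap.model import (
    PARAM_NAMES,
    ScalingModel,
    ScalingParameters,
    gauss_newton_sigma,
    negative_log_likelihood,
    scaled_mass,
)
from aprmap.synthetic import gen_reference_masses, SyntheticScenario
from aprmap.calibration_prep import prepare_reference


def _mass_tables(regions, truth, seed=0, n_countries=None, noise=0.0):
    """First-guess table plus exact forward-model reference masses."""
    rng = np.random.default_rng(seed)
    countries = regions.countries[:n_countries] if n_countries else regions.countries
    rows = []
    for crop in CALIBRATION_CROPS:
        for country in countries:
            rows.append(("H", crop, country, float(10 ** rng.uniform(3, 6))))
    m_tilde = pd.DataFrame(rows, columns=["major_group", "crop", "country", "mass_kg"])
    m_star = m_tilde.copy()
    m_star["mass_kg"] = [
        scaled_mass(truth, r.crop, r.country, r.mass_kg, regions)
        * 10 ** rng.normal(0.0, noise)
        for r in m_tilde.itertuples()
    ]
    return m_tilde, m_star


def _products(p: ScalingParameters) -> dict[str, float]:
    return {
        f"{c}*{r}": p.crop_factor(c) * p.region_factor(r)
        for c in CALIBRATION_CROPS
        for r in REGIONS
    }


class TestScaledMass:
    def test_all_ones_is_identity(self, regions):
        p = ScalingParameters()
        assert scaled_mass(p, "Corn", "Italy", 12345.0, regions) == pytest.approx(12345.0)

    def test_direct_product(self, regions):
        p = ScalingParameters(k_corn=2.0, k_seu=3.0, alpha=1.0)
        assert scaled_mass(p, "Corn", "Italy", 1e4, regions) == pytest.approx(6e4)

    def test_published_herbicide_row_hand_evaluation(self, regions):
        # wheat in a southern-Europe country: k_wheat * k_seu * (1e5)^alpha
        row = published_calibration().loc["H"]
        p = ScalingParameters(*[row[n] for n in PARAM_NAMES])
        expected = row["k_wheat"] * row["k_seu"] * 10 ** (5 * row["alpha"])
        assert scaled_mass(p, "Wheat", "Italy", 1e5, regions) == pytest.approx(expected)

    def test_nonpositive_mass_rejected(self, regions):
        with pytest.raises(ValueError):
            scaled_mass(ScalingParameters(), "Corn", "Italy", 0.0, regions)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            ScalingParameters(k_corn=-1.0)


class TestObjective:
    def test_perfect_fit_is_zero(self, regions):
        m_tilde, m_star = _mass_tables(regions, ScalingParameters(), seed=1)
        model = ScalingModel(m_star, m_tilde, regions, major_group="H")
        assert model.objective(ScalingParameters()) == pytest.approx(0.0, abs=1e-20)

    def test_one_decade_misfit_is_one(self, regions):
        m_tilde = pd.DataFrame(
            [("H", "Corn", "Italy", 1e4)],
            columns=["major_group", "crop", "country", "mass_kg"],
        )
        m_star = m_tilde.copy()
        m_star["mass_kg"] = 1e5
        model = ScalingModel(m_star, m_tilde, regions, major_group="H")
        assert model.objective(ScalingParameters()) == pytest.approx(1.0)

    def test_matches_term_by_term_oracle(self, regions):
        truth = ScalingParameters(0.8, 1.5, 2.0, 1.2, 0.9, 1.8, 0.95)
        m_tilde, m_star = _mass_tables(regions, truth, seed=2, n_countries=4, noise=0.3)
        model = ScalingModel(m_star, m_tilde, regions, major_group="H")
        p = ScalingParameters(1.1, 0.9, 1.3, 0.7, 1.4, 1.1, 1.02)
        total = 0.0
        for s_row, t_row in zip(m_star.itertuples(), m_tilde.itertuples()):
            pred = scaled_mass(p, t_row.crop, t_row.country, t_row.mass_kg, regions)
            total += (np.log10(s_row.mass_kg) - np.log10(pred)) ** 2
        assert model.objective(p) == pytest.approx(total, rel=1e-12)

    def test_no_overlap_rejected(self, regions):
        m_tilde = pd.DataFrame(
            [("H", "Corn", "Italy", 1e4)],
            columns=["major_group", "crop", "country", "mass_kg"],
        )
        m_star = pd.DataFrame(
            [("H", "Wheat", "France", 1e4)],
            columns=["major_group", "crop", "country", "mass_kg"],
        )
        with pytest.raises(ValueError, match="overlap"):
            ScalingModel(m_star, m_tilde, regions, major_group="H")


class TestGaugeInvariance:
    @settings(deadline=None, max_examples=25)
    @given(c=st.floats(min_value=0.1, max_value=10.0))
    def test_crop_region_rescaling_leaves_objective_unchanged(self, c):
        from aprmap.domain import load_regions

        regions = load_regions()
        truth = ScalingParameters(0.8, 1.5, 2.0, 1.2, 0.9, 1.8, 0.95)
        m_tilde, m_star = _mass_tables(regions, truth, seed=3, n_countries=5, noise=0.2)
        model = ScalingModel(m_star, m_tilde, regions, major_group="H")
        p = ScalingParameters(0.7, 1.1, 1.9, 1.0, 1.2, 0.8, 0.9)
        q = ScalingParameters(0.7 * c, 1.1 * c, 1.9 * c, 1.0 / c, 1.2 / c, 0.8 / c, 0.9)
        assert model.objective(q) == pytest.approx(model.objective(p), rel=1e-9)


class TestCalibrate:
    def test_all_ones_truth_recovered(self, regions):
        m_tilde, m_star = _mass_tables(regions, ScalingParameters(), seed=4)
        res = ScalingModel(m_star, m_tilde, regions, major_group="H").fit()
        for value in _products(res.params).values():
            assert value == pytest.approx(1.0, abs=1e-3)
        assert res.params.alpha == pytest.approx(1.0, abs=1e-3)

    def test_general_truth_products_recovered(self, regions):
        truth = ScalingParameters(0.6, 2.2, 1.4, 1.3, 0.75, 2.1, 0.9)
        m_tilde, m_star = _mass_tables(regions, truth, seed=5)
        res = ScalingModel(m_star, m_tilde, regions, major_group="H").fit()
        want = _products(truth)
        got = _products(res.params)
        for key in want:
            assert got[key] == pytest.approx(want[key], rel=1e-3)
        assert res.params.alpha == pytest.approx(truth.alpha, abs=1e-3)
        assert res.J_min < 1e-8

    def test_fit_never_worse_than_first_guess(self, regions):
        truth = ScalingParameters(1.4, 0.9, 1.1, 0.8, 1.3, 1.0, 1.05)
        m_tilde, m_star = _mass_tables(regions, truth, seed=6, noise=0.4)
        model = ScalingModel(m_star, m_tilde, regions, major_group="H")
        res = model.fit()
        assert res.J_min <= model.objective(ScalingParameters()) + 1e-12

    def test_two_parameter_subproblem_matches_grid_search(self, regions):
        # single crop x single region: only the product k_corn*k_seu and
        # alpha are active -> exhaustive 2-D grid search as oracle. The
        # log-mass regressor is centred so the two directions decouple and
        # the grid argmin is sharp.
        rng = np.random.default_rng(7)
        seu = [c for c in regions.countries if regions.region(c) == "SEU"]
        t = np.linspace(-1.5, 1.5, len(seu))
        m_tilde = pd.DataFrame(
            [("H", "Corn", c, float(10.0**ti)) for c, ti in zip(seu, t)],
            columns=["major_group", "crop", "country", "mass_kg"],
        )
        m_star = m_tilde.copy()
        m_star["mass_kg"] = 1.7 * m_tilde["mass_kg"] ** 0.88 * 10 ** rng.normal(0, 0.1, len(m_tilde))
        res = ScalingModel(m_star, m_tilde, regions, major_group="H").fit()

        y = np.log10(m_star["mass_kg"].to_numpy())
        log_p = np.linspace(0.0, 0.5, 801)
        alphas = np.linspace(0.7, 1.1, 801)
        P, A = np.meshgrid(log_p, alphas)
        J = ((y[None, None, :] - P[..., None] - A[..., None] * t[None, None, :]) ** 2).sum(-1)
        i, j = np.unravel_index(J.argmin(), J.shape)
        fitted_log_p = np.log10(res.params.k_corn * res.params.k_seu)
        assert fitted_log_p == pytest.approx(P[i, j], abs=log_p[1] - log_p[0])
        assert res.params.alpha == pytest.approx(A[i, j], abs=alphas[1] - alphas[0])
        assert res.J_min <= J.min() + 1e-9

    def test_pipeline_forward_model_recovery(self, regions, taxonomy):
        # forward generation at record granularity, then preparation and fit
        scenario = SyntheticScenario.small(seed=8, noise_sd_log10=0.0, sparsity=0.0)
        truth = scenario.truth_params["H"]
        m_tilde, _ = _mass_tables(regions, truth, seed=8)
        records, _, _ = gen_reference_masses(scenario, m_tilde, regions)
        m_star = prepare_reference(records, scenario.taxonomy(), window=scenario.years)
        res = ScalingModel(m_star, m_tilde, regions, major_group="H").fit()
        want, got = _products(truth), _products(res.params)
        for key in want:
            assert got[key] == pytest.approx(want[key], rel=1e-3)


class TestPosteriorSigma:
    def test_zero_noise_gives_vanishing_sigma(self, regions):
        truth = ScalingParameters(0.6, 2.2, 1.4, 1.3, 0.75, 2.1, 0.9)
        m_tilde, m_star = _mass_tables(regions, truth, seed=9)
        res = ScalingModel(m_star, m_tilde, regions, major_group="H").fit()
        assert (res.bse < 1e-4).all()

    def test_reduced_model_matches_closed_form_regression(self):
        # 1-parameter linear model y = b t: sigma_b = s / sqrt(sum t^2)
        t = np.array([1.0, 2.0, 3.0])
        y = np.array([1.1, 1.9, 3.2])
        b = (t @ y) / (t @ t)
        resid = y - b * t
        j_min = float(resid @ resid)
        sigma = gauss_newton_sigma(t[:, None], j_min, nobs=3)
        expected = np.sqrt(j_min / (3 - 1)) / np.sqrt(t @ t)
        assert sigma[0] == pytest.approx(expected, rel=1e-12)

    def test_sigma_scales_with_residuals(self):
        G = np.random.default_rng(0).random((10, 2)) + 0.5
        s1 = gauss_newton_sigma(G, 1.0, nobs=10)
        s2 = gauss_newton_sigma(G, 4.0, nobs=10)  # doubled residuals
        np.testing.assert_allclose(s2, 2 * s1)

    def test_too_few_observations_rejected(self, regions):
        m_tilde = pd.DataFrame(
            [("H", "Corn", c, 1e4) for c in regions.countries[:7]],
            columns=["major_group", "crop", "country", "mass_kg"],
        )
        m_star = m_tilde.copy()
        with pytest.raises(ValueError, match="observations"):
            ScalingModel(m_star, m_tilde, regions, major_group="H").fit()

    def test_covariance_symmetric_psd(self, regions):
        truth = ScalingParameters(0.9, 1.2, 1.5, 1.1, 0.8, 1.4, 0.95)
        m_tilde, m_star = _mass_tables(regions, truth, seed=10, noise=0.2)
        res = ScalingModel(m_star, m_tilde, regions, major_group="H").fit()
        np.testing.assert_allclose(res.cov_params, res.cov_params.T, atol=1e-12)
        eigenvalues = np.linalg.eigvalsh(res.cov_params)
        assert (eigenvalues > -1e-10).all()


class TestNegativeLogLikelihood:
    def test_constructed_zero(self):
        j = 2.0 / (2.0 * np.pi * np.e)
        assert negative_log_likelihood(j, 2) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_j(self):
        values = [negative_log_likelihood(j, 50) for j in (0.5, 1.0, 2.0, 10.0)]
        assert values == sorted(values)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(2, 200))
            j = float(rng.uniform(0.01, 100))
            expected = n / 2 * (np.log(2 * np.pi * j / n) + 1)
            assert negative_log_likelihood(j, n) == pytest.approx(expected, rel=1e-12)

    def test_perfect_fit_sentinel(self):
        assert negative_log_likelihood(0.0, 10) == float("-inf")


class TestResultsSurface:
    def test_summary_mentions_parameters_and_gauge(self, regions):
        truth = ScalingParameters()
        m_tilde, m_star = _mass_tables(regions, truth, seed=11, noise=0.1)
        res = ScalingModel(m_star, m_tilde, regions, major_group="H").fit()
        text = res.summary()
        for name in PARAM_NAMES:
            assert name in text
        assert "identifiable" in text

    def test_fittedvalues_align_with_keys(self, regions):
        m_tilde, m_star = _mass_tables(regions, ScalingParameters(), seed=12)
        res = ScalingModel(m_star, m_tilde, regions, major_group="H").fit()
        fitted = res.fittedvalues
        assert len(fitted) == res.nobs
        assert set(fitted.columns) == {"major_group", "crop", "country", "mass_kg"}
        assert (fitted["mass_kg"] > 0).all()
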