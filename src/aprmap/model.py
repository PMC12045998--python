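"""Maximum-likelihood calibration of the crop/region mass-scaling model.

For one pesticide major group, the applied mass per (crop, country) is
modelled as a power-law rescaling of the first-guess mass:

    m(crop, country) = k_C(crop) * k_L(region(country)) * m~(crop, country)^alpha

with one multiplicative factor per calibration crop (Corn, Wheat, AOC), one
per region (SEU, CEU, NEU), and a shared exponent alpha. Parameters are
estimated by least squares on decadic log residuals,

    J(k) = sum_i (log10 m*_i - log10 m_i(k))^2,

minimised by bounded gradient descent from the all-ones start (so the first
guess is the starting model). The model is gauge-degenerate: multiplying
all crop factors by c and dividing all region factors by c leaves the fit
unchanged, so only the products k_C * k_L and alpha are identifiable; the
posterior covariance is therefore computed through a pseudo-inverse of the
Gauss-Newton normal matrix.

Usage follows the familiar model/results pattern::

    model = ScalingModel(m_star, m_tilde, regions)
    res = model.fit()
    print(res.summary())
    draws = res.sample_parameters(1000, seed=7)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.optimize

from .domain import CALIBRATION_CROPS, REGIONS, RegionAssignment, published_calibration

logger = logging.getLogger("aprmap.model")

__all__ = ["ScalingParameters", "ScalingModel", "CalibrationResults", "PARAM_NAMES"]

PARAM_NAMES = ("k_corn", "k_wheat", "k_aoc", "k_seu", "k_ceu", "k_neu", "alpha")

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class ScalingParameters:
    """The seven-parameter vector (crop factors, region factors, exponent)."""

    k_corn: float = 1.0
    k_wheat: float = 1.0
    k_aoc: float = 1.0
    k_seu: float = 1.0
    k_ceu: float = 1.0
    k_neu: float = 1.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("all scaling parameters must be positive and finite")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ScalingParameters":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (7,):
            raise ValueError("expected 7 parameters")
        return cls(**dict(zip(PARAM_NAMES, arr)))

    def crop_factor(self, crop: str) -> float:
        return {"Corn": self.k_corn, "Wheat": self.k_wheat, "AOC": self.k_aoc}[crop]

    def region_factor(self, region: str) -> float:
        return {"SEU": self.k_seu, "CEU": self.k_ceu, "NEU": self.k_neu}[region]


def scaled_mass(
    p: ScalingParameters,
    crop: str,
    country: str,
    m_tilde: float,
    regions: RegionAssignment,
) -> float:
    """Evaluate the scaling model for a single (crop, country) mass."""
    if m_tilde <= 0:
        raise ValueError("first-guess mass must be positive")
    return (
        p.crop_factor(crop)
        * p.region_factor(regions.region(country))
        * m_tilde**p.alpha
    )


class ScalingModel:
    """Scaling-model calibration for one major group.

    Parameters
    ----------
    m_star : DataFrame
        Reference masses with columns (major_group, crop, country, mass_kg)
        or (crop, country, mass_kg); one major group only.
    m_tilde : DataFrame
        First-guess masses, same layout.
    regions : RegionAssignment
        Country -> SEU/CEU/NEU partition.

    Keys present in only one of the two tables are skipped (their count is
    logged), mirroring the restriction of the objective to available data.
    """

    def __init__(
        self,
        m_star: pd.DataFrame,
        m_tilde: pd.DataFrame,
        regions: RegionAssignment,
        major_group: str | None = None,
    ):
        star = self._narrow(m_star, major_group, "m_star")
        tilde = self._narrow(m_tilde, major_group, "m_tilde")
        self.major_group = major_group
        self.regions = regions

        merged = star.merge(
            tilde, on=["crop", "country"], suffixes=("_star", "_tilde"), how="inner"
        )
        n_skipped = (len(star) - len(merged)) + (len(tilde) - len(merged))
        if n_skipped:
            logger.info("skipped %d keys present in only one mass table", n_skipped)
        if len(merged) == 0:
            raise ValueError("no overlapping (crop, country) keys between the tables")
        if (merged["mass_kg_star"] <= 0).any() or (merged["mass_kg_tilde"] <= 0).any():
            raise ValueError("masses must be strictly positive on overlapping keys")
        bad = set(merged["crop"]) - set(CALIBRATION_CROPS)
        if bad:
            raise ValueError(f"unknown calibration crops {sorted(bad)}")

        merged = merged.sort_values(["crop", "country"], ignore_index=True)
        self.data = merged
        self.n_skipped = n_skipped
        self.crop_idx = merged["crop"].map(
            {c: i for i, c in enumerate(CALIBRATION_CROPS)}
        ).to_numpy()
        self.region_idx = (
            merged["country"].map(regions.region).map(
                {r: i for i, r in enumerate(REGIONS)}
            ).to_numpy()
        )
        self.log_m_star = np.log10(merged["mass_kg_star"].to_numpy(dtype=float))
        self.log_m_tilde = np.log10(merged["mass_kg_tilde"].to_numpy(dtype=float))

    @staticmethod
    def _narrow(df: pd.DataFrame, major_group: str | None, name: str) -> pd.DataFrame:
        required = {"crop", "country", "mass_kg"}
        if not required.issubset(df.columns):
            raise ValueError(f"{name} needs columns {sorted(required)}")
        if "major_group" in df.columns:
            groups = df["major_group"].unique()
            if major_group is not None:
                df = df[df["major_group"] == major_group]
            elif len(groups) > 1:
                raise ValueError(
                    f"{name} holds several major groups {sorted(groups)}; "
                    "pass major_group explicitly"
                )
        return df[["crop", "country", "mass_kg"]].copy()

    @property
    def nobs(self) -> int:
        return len(self.data)

    # --- objective ---------------------------------------------------------

    def _log_residuals(self, x: np.ndarray) -> np.ndarray:
        log_k = np.log10(x[:6])
        alpha = x[6]
        pred = log_k[self.crop_idx] + log_k[3 + self.region_idx] + alpha * self.log_m_tilde
        return self.log_m_star - pred

    def objective(self, p: ScalingParameters | np.ndarray) -> float:
        """Sum of squared decadic-log misfits J over the available keys."""
        x = p.as_array() if isinstance(p, ScalingParameters) else np.asarray(p, float)
        r = self._log_residuals(x)
        return float(r @ r)

    def _objective_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        r = self._log_residuals(x)
        g = np.zeros(7)
        for i in range(3):
            g[i] = -2.0 * r[self.crop_idx == i].sum() / (x[i] * _LN10)
        for i in range(3):
            g[3 + i] = -2.0 * r[self.region_idx == i].sum() / (x[3 + i] * _LN10)
        g[6] = -2.0 * float(r @ self.log_m_tilde)
        return float(r @ r), g

    def _jacobian(self, x: np.ndarray) -> np.ndarray:
        """Jacobian of the log10-model predictions w.r.t. the parameters."""
        n = self.nobs
        G = np.zeros((n, 7))
        rows = np.arange(n)
        G[rows, self.crop_idx] = 1.0 / (x[self.crop_idx] * _LN10)
        G[rows, 3 + self.region_idx] = 1.0 / (x[3 + self.region_idx] * _LN10)
        G[:, 6] = self.log_m_tilde
        return G

    def predict(self, p: ScalingParameters) -> pd.DataFrame:
        """Model masses m(p) on the calibration keys."""
        x = p.as_array()
        pred = 10.0 ** (
            np.log10(x[:3])[self.crop_idx]
            + np.log10(x[3:6])[self.region_idx]
            + x[6] * self.log_m_tilde
        )
        out = self.data[["crop", "country"]].copy()
        if self.major_group is not None:
            out.insert(0, "major_group", self.major_group)
        out["mass_kg"] = pred
        return out

    # --- fitting -----------------------------------------------------------

    def fit(
        self,
        start: ScalingParameters | None = None,
        k_bounds: tuple[float, float] = (1e-3, 1e3),
        alpha_bounds: tuple[float, float] = (0.1, 2.0),
        tol: float = 1e-10,
        maxiter: int = 10_000,
    ) -> "CalibrationResults":
        """Bounded local minimisation of J from the all-ones start."""
        x0 = (start or ScalingParameters()).as_array()
        bounds = [k_bounds] * 6 + [alpha_bounds]
        opt = scipy.optimize.minimize(
            self._objective_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-12, "maxiter": maxiter, "maxfun": 10 * maxiter},
        )
        if not np.all(np.isfinite(opt.x)):
            raise RuntimeError(f"optimizer failed: {opt.message}")
        k_hat = ScalingParameters.from_array(opt.x)
        j_min = float(opt.fun)
        sigma, cov = self._posterior_sigma(opt.x, j_min)
        return CalibrationResults(
            model=self,
            params=k_hat,
            J_min=j_min,
            bse=sigma,
            cov_params=cov,
            nobs=self.nobs,
            converged=bool(opt.success),
            optimizer_message=str(opt.message),
        )

    def _posterior_sigma(self, x: np.ndarray, j_min: float):
        """Gauss-Newton posterior covariance at the optimum.

        cov = s^2 (G'G)^+ with s^2 = J_min/(n - 7); the pseudo-inverse
        accommodates the crop/region gauge degeneracy of the normal matrix.
        """
        n, p = self.nobs, 7
        if n <= p:
            raise ValueError(f"need more than {p} observations for posterior sigma (got {n})")
        G = self._jacobian(x)
        gtg = G.T @ G
        s2 = j_min / (n - p)
        cond = np.linalg.cond(gtg)
        if cond > 1e12:
            logger.warning(
                "normal matrix is singular to working precision (cond=%.2e); "
                "using pseudo-inverse (gauge degeneracy of crop/region factors)",
                cond,
            )
        cov = s2 * np.linalg.pinv(gtg, hermitian=True)
        sigma = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return sigma, cov


def gauss_newton_sigma(G: np.ndarray, j_min: float, nobs: int) -> np.ndarray:
    """Standalone Gauss-Newton standard errors for an arbitrary residual
    Jacobian (used for reduced models and cross-checks)."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    n_params = G.shape[1]
    if nobs <= n_params:
        raise ValueError("need nobs > n_params")
    s2 = j_min / (nobs - n_params)
    cov = s2 * np.linalg.pinv(G.T @ G, hermitian=True)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def negative_log_likelihood(j_min: float, nobs: int) -> float:
    """Gaussian NLL at the optimum with the ML variance J_min/n.

    A perfect fit (J_min = 0) has no finite ML variance; the documented
    sentinel -inf is returned.
    """
    if nobs <= 0:
        raise ValueError("nobs must be positive")
    if j_min < 0:
        raise ValueError("J_min must be nonnegative")
    if j_min == 0.0:
        return float("-inf")
    s2_ml = j_min / nobs
    return 0.5 * nobs * (np.log(2.0 * np.pi * s2_ml) + 1.0)


@dataclass
class CalibrationResults:
    """Fit results: estimates, posterior spread, misfit and diagnostics."""

    model: ScalingModel
    params: ScalingParameters
    J_min: float
    bse: np.ndarray
    cov_params: np.ndarray
    nobs: int
    converged: bool
    optimizer_message: str = ""

    @property
    def nll(self) -> float:
        return negative_log_likelihood(self.J_min, self.nobs)

    @property
    def fittedvalues(self) -> pd.DataFrame:
        """ML best-estimate masses m^ on the calibration keys."""
        return self.model.predict(self.params)

    @property
    def resid(self) -> np.ndarray:
        """Decadic-log residuals log10 m* - log10 m^."""
        return self.model._log_residuals(self.params.as_array())

    def identifiable_products(self) -> dict[str, float]:
        """The gauge-invariant crop x region factor products."""
        p = self.params
        return {
            f"{c}*{r}": p.crop_factor(c) * p.region_factor(r)
            for c in CALIBRATION_CROPS
            for r in REGIONS
        }

    def sample_parameters(self, n: int = 1000, seed: int | None = None) -> np.ndarray:
        """Independent normal parameter draws around the estimates.

        Non-positive draws are rejected and re-drawn (the model needs
        positive factors). Returns an (n, 7) array.
        """
        from .montecarlo import sample_parameters

        return sample_parameters(self.params, self.bse, n=n, seed=seed)

    def simulate_scenarios(
        self, m_tilde: pd.DataFrame, n: int = 1000, seed: int | None = None
    ) -> pd.DataFrame:
        """Monte-Carlo Low/Median/High scenario masses on the given keys."""
        from .montecarlo import propagate, scenario_quartiles, sample_parameters

        draws = sample_parameters(self.params, self.bse, n=n, seed=seed)
        keys, samples = propagate(draws, m_tilde, self.model.regions)
        return scenario_quartiles(keys, samples, seed=seed)

    def summary(self) -> str:
        lines = [
            "Scaling-model calibration results",
            "=" * 58,
            f"Major group:        {self.model.major_group or '-'}",
            f"N observations:     {self.nobs}"
            + (f"   (skipped keys: {self.model.n_skipped})" if self.model.n_skipped else ""),
            f"J at optimum:       {self.J_min:.6g}",
            f"NLL:                {self.nll:.4g}",
            f"Converged:          {self.converged}",
            "-" * 58,
            f"{'parameter':<12}{'estimate':>12}{'post. sd':>12}",
        ]
        for name, est, sd in zip(PARAM_NAMES, self.params.as_array(), self.bse):
            lines.append(f"{name:<12}{est:>12.4f}{sd:>12.4f}")
        lines.append("-" * 58)
        lines.append("note: only k_C*k_L products and alpha are identifiable")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "major_group": self.model.major_group,
            "params": dict(zip(PARAM_NAMES, self.params.as_array().tolist())),
            "sigma": dict(zip(PARAM_NAMES, np.asarray(self.bse).tolist())),
            "J_min": self.J_min,
            "nll": self.nll,
            "n_obs": self.nobs,
            "converged": self.converged,
        }

    @classmethod
    def from_published(
        cls, major_group: str, regions: RegionAssignment | None = None
    ) -> "PublishedCalibration":
        """Calibration summary built from the published parameter table
        (no data attached; supports sampling and scenario simulation)."""
        row = published_calibration().loc[major_group]
        params = ScalingParameters(
            *[float(row[n]) for n in PARAM_NAMES]
        )
        sigma = np.array(
            [float(row["sigma_" + n]) for n in PARAM_NAMES]
        )
        return PublishedCalibration(
            major_group=major_group,
            params=params,
            bse=sigma,
            nll=float(row["nll"]),
            regions=regions,
        )


@dataclass
class PublishedCalibration:
    """Parameter estimates and posterior spreads taken from a results table
    rather than a fit; enough structure for uncertainty propagation."""

    major_group: str
    params: ScalingParameters
    bse: np.ndarray
    nll: float
    regions: RegionAssignment | None = None

    def sample_parameters(self, n: int = 1000, seed: int | None = None) -> np.ndarray:
        from .montecarlo import sample_parameters

        return sample_parameters(self.params, self.bse, n=n, seed=seed)
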