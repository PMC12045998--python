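"""Monte-Carlo propagation of calibration uncertainty to mass scenarios.

Parameter estimates are treated as independent normals centred on the best
estimates with the posterior standard deviations as spread (independence is
a deliberate, cautionary simplification: correlations would confine the
sampled space). Each draw is pushed through the scaling model on every
(crop, country) key, and the first quartile, median and third quartile of
the resulting mass sample become the Low/Median/High scenarios. A
convergence check compares the three statistics across checkpoint sample
sizes; the default 10^3 realizations keeps their relative variation within
a few percent.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .domain import RegionAssignment
from .model import ScalingParameters

logger = logging.getLogger("aprmap.montecarlo")

__all__ = [
    "sample_parameters",
    "propagate",
    "scenario_quartiles",
    "convergence_check",
    "DEFAULT_N_REALIZATIONS",
]

DEFAULT_N_REALIZATIONS = 1000


def sample_parameters(
    params: ScalingParameters,
    sigma: np.ndarray,
    n: int = DEFAULT_N_REALIZATIONS,
    seed: int | None = None,
) -> np.ndarray:
    """Draw (n, 7) independent normal parameter vectors; non-positive values
    are rejected and re-drawn so every draw is a valid parameter vector."""
    mean = params.as_array()
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (7,):
        raise ValueError("sigma must have 7 entries")
    if np.any(~np.isfinite(sigma)) or np.any(sigma < 0):
        raise ValueError("sigma must be finite and nonnegative")
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean, sigma, size=(int(n), 7))
    for _ in range(1000):
        bad = draws <= 0
        if not bad.any():
            break
        idx = np.nonzero(bad)
        draws[idx] = rng.normal(mean[idx[1]], sigma[idx[1]])
    else:  # pragma: no cover - would need sigma >> mean
        raise RuntimeError("could not draw positive parameters after 1000 rounds")
    return draws


def propagate(
    draws: np.ndarray,
    m_tilde: pd.DataFrame,
    regions: RegionAssignment,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Evaluate the scaling model for every draw on every first-guess key.

    Returns the key table (rows of ``m_tilde`` with positive mass) and an
    (n_draws, n_keys) sample array. Keys with non-positive first-guess mass
    are skipped with a log message.
    """
    draws = np.asarray(draws, dtype=float)
    keys = m_tilde.reset_index(drop=True)
    usable = keys["mass_kg"] > 0
    if (~usable).any():
        logger.info("skipped %d keys with non-positive first-guess mass", int((~usable).sum()))
        keys = keys[usable].reset_index(drop=True)

    crop_map = {"Corn": 0, "Wheat": 1, "AOC": 2}
    region_map = {"SEU": 3, "CEU": 4, "NEU": 5}
    ci = keys["crop"].map(crop_map).to_numpy()
    ri = keys["country"].map(regions.region).map(region_map).to_numpy()
    log_mt = np.log10(keys["mass_kg"].to_numpy(dtype=float))

    k_crop = draws[:, ci]          # (n, keys)
    k_region = draws[:, ri]
    alpha = draws[:, 6][:, None]
    samples = k_crop * k_region * 10.0 ** (alpha * log_mt[None, :])
    return keys, samples


def scenario_quartiles(
    keys: pd.DataFrame,
    samples: np.ndarray,
    seed: int | None = None,
) -> pd.DataFrame:
    """Low/Median/High scenario masses as Q1/Q2/Q3 of the sample per key.

    Quantiles use linear interpolation between order statistics.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 4:
        raise ValueError("need at least 4 realizations")
    q = np.quantile(samples, [0.25, 0.5, 0.75], axis=0, method="linear")
    out = keys.copy()
    out["m_low"], out["m_median"], out["m_high"] = q[0], q[1], q[2]
    out["n_realizations"] = samples.shape[0]
    out["seed"] = seed if seed is not None else -1
    if not (
        (out["m_low"] <= out["m_median"] + 1e-12).all()
        and (out["m_median"] <= out["m_high"] + 1e-12).all()
    ):  # pragma: no cover - quantiles are monotone by construction
        raise AssertionError("scenario quartiles out of order")
    return out


def convergence_check(
    samples: np.ndarray,
    checkpoints=(250, 500, 1000),
) -> dict:
    """Relative variation of Q1/median/Q3 across growing sample sizes.

    For successive checkpoint sizes n_(k-1), n_k the statistics of the first
    n samples are compared: |s(n_k) - s(n_(k-1))| / s(n_(k-1)). Returns the
    per-key maximum, the maximum over all keys and statistics, and an
    aggregate (total mass over keys) variant.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    checkpoints = sorted(int(c) for c in checkpoints)
    if len(checkpoints) < 2:
        raise ValueError("need at least two checkpoints")
    if checkpoints[-1] > samples.shape[0]:
        raise ValueError("checkpoint exceeds sample size")

    stats = []       # (n_checkpoints, 3, n_keys)
    agg_stats = []   # (n_checkpoints, 3)
    for c in checkpoints:
        q = np.quantile(samples[:c], [0.25, 0.5, 0.75], axis=0, method="linear")
        stats.append(q)
        agg_stats.append(np.quantile(samples[:c].sum(axis=1), [0.25, 0.5, 0.75], method="linear"))
    stats = np.stack(stats)
    agg_stats = np.stack(agg_stats)
    if np.any(stats[:-1] == 0) or np.any(agg_stats[:-1] == 0):
        raise ValueError("relative variation undefined: a checkpoint statistic is zero")

    rel = np.abs(np.diff(stats, axis=0)) / np.abs(stats[:-1])
    agg_rel = np.abs(np.diff(agg_stats, axis=0)) / np.abs(agg_stats[:-1])
    per_key = rel.max(axis=(0, 1))
    return {
        "checkpoints": checkpoints,
        "per_key_max": per_key,
        "max": float(per_key.max()),
        "aggregate_max": float(agg_rel.max()),
    }
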