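"""MacKenzie-Bailey chi-square goodness of fit with posterior-predictive
simulation.

Sites are grouped into cohorts sharing the same missingness pattern. Within
a cohort every possible detection history h over the observed occasions is
enumerable (K <= 8 gives at most 256), and its expected frequency under the
model is E_h = sum_i Pr(history = h | params, site i); the statistic is
X^2 = sum_cohorts sum_h (O_h - E_h)^2 / E_h, with low-expectation cells
pooled into a residual cell. The test simulates a replicate dataset per
posterior draw and reports the fraction of draws where the replicate
statistic is at least the observed one — the posterior-predictive p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit

from .covariates import StandardizedCovariates
from .history import DetectionHistory
from .model import (
    FitDesign,
    ModelSpec,
    OccupancyParams,
    PosteriorFit,
    build_design,
    _params_to_theta,
    _unpack,
)


@dataclass
class GofResult:
    observed_stat: float  # posterior mean of per-draw observed statistics
    observed_stats: np.ndarray
    sim_stats: np.ndarray
    p_value: float
    n_sim: int
    cohort_table: pd.DataFrame  # observed/expected at the posterior-mean draw


def _marginal_psi(
    d: FitDesign, pars: dict[str, np.ndarray], alpha_by_site: np.ndarray | None,
    quad_points: int = 20,
) -> np.ndarray:
    """Per-site occupancy probability; marginal over the station intercept
    when no explicit alphas are supplied (detection does not depend on alpha,
    so history probabilities only need E_alpha[psi])."""
    eta = pars["beta0"][0] + d.Xpsi @ pars["beta"][0]
    if alpha_by_site is not None:
        return expit(eta + alpha_by_site)
    sigma = float(pars["sigma"][0])
    if sigma == 0:
        return expit(eta)
    x, w = hermgauss(quad_points)
    wbar = w / math.sqrt(math.pi)
    return np.sum(
        wbar * expit(eta[:, None] + math.sqrt(2.0) * sigma * x[None, :]), axis=1
    )


def _p_matrix(d: FitDesign, pars: dict[str, np.ndarray]) -> np.ndarray:
    eta = pars["gamma0"][0] + pars["gamma_effort"][0] * d.eff_z
    if d.use_survey and d.survey_dummies is not None:
        eta = eta + (d.survey_dummies @ pars["survey"][0])[:, None]
    return expit(eta)


def _chisq_from_probs(
    y01: np.ndarray,
    obs: np.ndarray,
    psi: np.ndarray,
    p: np.ndarray,
    pool_floor: float,
    want_table: bool = False,
) -> tuple[float, pd.DataFrame | None]:
    """The cohort-enumerated statistic for one parameter value."""
    patterns = [tuple(row) for row in obs]
    stat = 0.0
    rows = []
    seen: dict[tuple, np.ndarray] = {}
    for pat in set(patterns):
        idx = np.array([i for i, q in enumerate(patterns) if q == pat])
        kc = int(sum(pat))
        if kc == 0:
            continue  # cohort with no effort carries no information
        cols = np.flatnonzero(np.array(pat))
        H = 1 << kc
        bits = ((np.arange(H)[:, None] >> np.arange(kc)[None, :]) & 1).astype(float)
        logp = np.log(np.clip(p[np.ix_(idx, cols)], 1e-300, 1.0))
        log1mp = np.log(np.clip(1.0 - p[np.ix_(idx, cols)], 1e-300, 1.0))
        logD = bits @ logp.T + (1.0 - bits) @ log1mp.T  # (H, n_c)
        D = np.exp(logD)
        psi_c = psi[idx]
        E = D @ psi_c  # (H,)
        E[0] += np.sum(1.0 - psi_c)  # all-zero history also arises from absence
        codes = (y01[np.ix_(idx, cols)] @ (1 << np.arange(kc))).astype(int)
        O = np.bincount(codes, minlength=H).astype(float)
        # pool low-expectation cells into one residual cell
        small = E < pool_floor
        keep = ~small
        Ok, Ek = O[keep], E[keep]
        contrib = float(np.sum((Ok - Ek) ** 2 / np.where(Ek > 0, Ek, 1.0)))
        Op, Ep = float(O[small].sum()), float(E[small].sum())
        if Ep > 1e-12:
            contrib += (Op - Ep) ** 2 / Ep
        elif Op > 0:
            contrib = np.inf  # observed data impossible under the params
        stat += contrib
        if want_table:
            for h in np.flatnonzero(keep):
                rows.append(
                    {
                        "cohort": "".join("1" if b else "0" for b in pat),
                        "history": format(h, f"0{kc}b")[::-1],
                        "observed": float(O[h]),
                        "expected": float(E[h]),
                    }
                )
            if small.any():
                rows.append(
                    {
                        "cohort": "".join("1" if b else "0" for b in pat),
                        "history": "pooled",
                        "observed": Op,
                        "expected": Ep,
                    }
                )
    table = pd.DataFrame(rows) if want_table else None
    return stat, table


def mb_chisq(
    params: OccupancyParams,
    history: DetectionHistory,
    cov: StandardizedCovariates,
    spec: ModelSpec,
    pool_floor: float = 2.0,
    want_table: bool = True,
) -> tuple[float, pd.DataFrame | None]:
    """Observed-data MacKenzie-Bailey X^2 at one fixed parameter value.

    If ``params.alpha`` supplies station intercepts they are used; otherwise
    a positive ``sigma_station`` is integrated out. Cells with expected
    frequency below ``pool_floor`` are pooled into a residual cell per
    cohort; a residual cell with zero expectation but positive observations
    yields an infinite statistic (the data are impossible under the params).
    """
    d = build_design(history, cov, spec)
    theta = _params_to_theta(params, d)
    pars = _unpack(theta, d)
    if params.alpha:
        alpha = np.array([params.alpha.get(s, 0.0) for s in d.stations])
    else:
        alpha = None
    psi = _marginal_psi(d, pars, alpha)
    p = _p_matrix(d, pars)
    return _chisq_from_probs(d.y01, d.obs, psi, p, pool_floor, want_table)


def mb_gof_test(
    fit: PosteriorFit,
    history: DetectionHistory,
    cov: StandardizedCovariates,
    spec: ModelSpec,
    n_sim: int = 1000,
    seed: int = 0,
    pool_floor: float = 2.0,
) -> GofResult:
    """Posterior-predictive MacKenzie-Bailey test.

    For each of ``n_sim`` posterior draws the observed-data statistic is
    computed at that draw, a replicate dataset is simulated from the same
    draw (fresh station intercepts, latent states, detections on the
    observed effort pattern), and the replicate statistic is computed; the
    p-value is the fraction of paired draws with replicate >= observed.
    """
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives an unstable p-value", stacklevel=2)
    d = fit.design
    rng = np.random.default_rng(seed)
    n_draws = fit.n_draws
    take = (
        np.arange(n_draws)
        if n_sim >= n_draws
        else rng.choice(n_draws, size=n_sim, replace=False)
    )
    uniq_stations, codes = np.unique(d.stations, return_inverse=True)
    obs_stats = np.empty(len(take))
    sim_stats = np.empty(len(take))
    for j, i in enumerate(take):
        theta = fit.draws[i][None, :]
        pars = _unpack(theta, d)
        psi_marg = _marginal_psi(d, pars, None)
        p = _p_matrix(d, pars)
        obs_stats[j], _ = _chisq_from_probs(
            d.y01, d.obs, psi_marg, p, pool_floor, want_table=False
        )
        sigma = float(pars["sigma"][0])
        alpha = rng.normal(0.0, sigma, size=len(uniq_stations))[codes]
        eta = pars["beta0"][0] + d.Xpsi @ pars["beta"][0] + alpha
        z = rng.binomial(1, expit(eta))
        y_rep = np.where(d.obs, rng.binomial(1, p * z[:, None]), 0.0)
        sim_stats[j], _ = _chisq_from_probs(
            y_rep, d.obs, psi_marg, p, pool_floor, want_table=False
        )
    p_value = float(np.mean(sim_stats >= obs_stats))

    mean_params = fit.draws.mean(axis=0)[None, :]
    pars = _unpack(mean_params, d)
    _, table = _chisq_from_probs(
        d.y01,
        d.obs,
        _marginal_psi(d, pars, None),
        _p_matrix(d, pars),
        pool_floor,
        want_table=True,
    )
    return GofResult(
        observed_stat=float(np.mean(obs_stats)),
        observed_stats=obs_stats,
        sim_stats=sim_stats,
        p_value=p_value,
        n_sim=len(take),
        cohort_table=table,
    )
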