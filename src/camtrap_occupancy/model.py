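"""Bayesian single-season occupancy model with imperfect detection.

The model: each stacked site i (a camera-station x year) has a latent
presence state ``z_i ~ Bernoulli(psi_i)`` with

    logit(psi_i) = beta0 + sum_j beta_j * x_ij + alpha_station(i),

and conditional on presence each occasion t yields a detection
``y_it ~ Bernoulli(p_it)`` with

    logit(p_it) = gamma0 + gamma_effort * e_it + delta_survey(i),

where ``x`` are z-scored site covariates, ``e`` is z-scored per-occasion
trapping effort and the survey factor absorbs heterogeneity between source
databases (reference level fixed at 0). Occasions without effort are missing
and contribute no factor.

The latent state is always marginalized analytically, so the per-site
likelihood is the familiar Bernoulli mixture

    L_i = psi_i * prod_t p_it^y_it (1-p_it)^(1-y_it) + (1-psi_i) * I[no detections].

The optional station random intercept ``alpha ~ Normal(0, sigma)`` (shared by
the site-years of one station, absorbing the pseudoreplication introduced by
stacking) is integrated out by Gauss-Hermite quadrature, which keeps the
sampled parameter space low-dimensional; posterior sampling uses the emcee
affine-invariant ensemble, with walkers grouped into chains for split-R-hat
diagnostics. Any sampler reproducing the convergence and parameter-recovery
suites would be an equally valid backend.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import log_expit, logsumexp

from .covariates import StandardizedCovariates
from .history import DetectionHistory
from .synthetic import SURVEY_REFERENCE


class SchemaError(KeyError):
    """A model term is absent from the covariate table."""


@dataclass
class PriorSpec:
    """Weakly-informative default priors on the logit scale.

    Slopes act on z-scored predictors, so a scale of 2.5 is diffuse;
    intercept scale 5 spans essentially all of (0, 1) after the inverse
    logit; the random-intercept SD gets a half-normal with scale 2.5.
    """

    slope_scale: float = 2.5
    intercept_scale: float = 5.0
    sigma_scale: float = 2.5

    def __post_init__(self) -> None:
        if min(self.slope_scale, self.intercept_scale, self.sigma_scale) <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class ModelSpec:
    """Which terms enter the occupancy (psi) and detection (p) predictors."""

    psi_terms: list[str] = field(default_factory=list)
    p_terms: list[str] = field(default_factory=list)  # subset of {"effort","survey"}
    random_station_intercept: bool = False
    priors: PriorSpec = field(default_factory=PriorSpec)
    label: str = ""

    def __post_init__(self) -> None:
        bad = set(self.p_terms) - {"effort", "survey"}
        if bad:
            raise ValueError(f"unknown detection terms: {sorted(bad)}")
        if not self.label:
            psi = "+".join(self.psi_terms) if self.psi_terms else "."
            p = "+".join(self.p_terms) if self.p_terms else "."
            ri = "+RI" if self.random_station_intercept else ""
            self.label = f"P({p})psi({psi}){ri}"

    def without(self, term: str) -> "ModelSpec":
        return replace(
            self,
            psi_terms=[t for t in self.psi_terms if t != term],
            label="",
        )


@dataclass
class OccupancyParams:
    """One concrete parameter value (a posterior draw or the truth)."""

    beta0: float = 0.0
    beta: dict[str, float] = field(default_factory=dict)
    alpha: dict[str, float] = field(default_factory=dict)
    sigma_station: float = 0.0
    gamma0: float = 0.0
    gamma_effort: float = 0.0
    survey_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma_station < 0:
            raise ValueError("sigma_station must be >= 0")


def site_marginal_likelihood(psi, p, y) -> float:
    """Marginal likelihood of one site's detection history.

    ``psi * prod_t p_t^y_t (1-p_t)^(1-y_t) + (1-psi) * I[all observed y_t == 0]``
    with missing occasions (None/NaN) skipped.
    """
    prod = 1.0
    all_zero = True
    for pt, yt in zip(p, y):
        if yt is None or (isinstance(yt, float) and math.isnan(yt)):
            continue
        if yt == 1:
            prod *= pt
            all_zero = False
        elif yt == 0:
            prod *= 1.0 - pt
        else:
            raise ValueError(f"invalid detection value {yt!r}")
    return psi * prod + (1.0 - psi) * (1.0 if all_zero else 0.0)


# ---------------------------------------------------------------------------
# design construction


@dataclass
class FitDesign:
    """Aligned numeric arrays the likelihood works on (sites sorted by
    (station_id, year) so each station's rows are contiguous)."""

    site_index: list[tuple[str, int]]
    Xpsi: np.ndarray  # (S, P) z-scored occupancy covariates
    psi_names: list[str]
    y01: np.ndarray  # (S, K) with 0 in missing cells
    obs: np.ndarray  # (S, K) bool
    no_det: np.ndarray  # (S,) no observed detection
    eff_z: np.ndarray  # (S, K) z-scored effort, 0 in missing cells
    effort_mean: float
    effort_sd: float
    survey_dummies: np.ndarray | None  # (S, L-1)
    survey_offset_levels: list[str]
    survey_reference: str
    stations: np.ndarray  # (S,) station id strings
    station_starts: np.ndarray  # group starts for reduceat
    use_effort: bool
    use_survey: bool
    random_intercept: bool
    param_names: list[str]
    transform_params: dict[str, tuple[float, float]]

    @property
    def n_sites(self) -> int:
        return self.y01.shape[0]


def build_design(
    history: DetectionHistory,
    cov: StandardizedCovariates,
    spec: ModelSpec,
) -> FitDesign:
    df = cov.data
    for col in ("station_id", "year"):
        if col not in df.columns:
            raise SchemaError(f"covariate table lacks {col!r}")
    # a 'year' occupancy term resolves to the z-scored year_z column
    psi_cols = ["year_z" if t == "year" else t for t in spec.psi_terms]
    for term in psi_cols:
        if term not in df.columns:
            raise SchemaError(f"occupancy term {term!r} absent from covariate table")

    key_to_row = {
        (str(sid), int(yr)): i
        for i, (sid, yr) in enumerate(zip(df["station_id"], df["year"]))
    }
    # sort sites by (station, year) so station groups are contiguous
    order = sorted(
        range(history.n_sites), key=lambda i: (str(history.site_index[i][0]), int(history.site_index[i][1]))
    )
    site_index = [
        (str(history.site_index[i][0]), int(history.site_index[i][1])) for i in order
    ]
    rows = []
    for key in site_index:
        if key not in key_to_row:
            raise SchemaError(f"site {key} missing from covariate table")
        rows.append(key_to_row[key])
    df = df.iloc[rows].reset_index(drop=True)

    y = history.y[order]
    effort = history.effort[order]
    obs = effort > 0
    y01 = np.where(obs, np.nan_to_num(y), 0.0)
    no_det = y01.sum(axis=1) == 0

    Xpsi = (
        df[psi_cols].to_numpy(dtype=float)
        if psi_cols
        else np.zeros((len(df), 0))
    )

    eff_obs = effort[obs]
    e_mean = float(eff_obs.mean()) if eff_obs.size else 0.0
    e_sd = float(np.std(eff_obs, ddof=1)) if eff_obs.size > 1 else 1.0
    if e_sd == 0:
        e_sd = 1.0
    eff_z = np.zeros_like(effort, dtype=float)
    eff_z[obs] = (effort[obs] - e_mean) / e_sd

    use_survey = "survey" in spec.p_terms
    survey_dummies = None
    offset_levels: list[str] = []
    reference = SURVEY_REFERENCE
    if use_survey:
        if "survey" not in df.columns:
            raise SchemaError("detection term 'survey' absent from covariate table")
        levels = sorted(set(df["survey"].astype(str)))
        if reference not in levels:
            reference = levels[0]
        offset_levels = [lev for lev in levels if lev != reference]
        survey_dummies = np.stack(
            [(df["survey"].astype(str) == lev).to_numpy(float) for lev in offset_levels],
            axis=1,
        )

    stations = df["station_id"].astype(str).to_numpy()
    starts = np.flatnonzero(
        np.r_[True, stations[1:] != stations[:-1]]
    )

    names = ["beta0"] + [f"beta_{t}" for t in spec.psi_terms]
    if spec.random_station_intercept:
        names.append("log_sigma_station")
    names.append("gamma0")
    if "effort" in spec.p_terms:
        names.append("gamma_effort")
    names += [f"survey_{lev}" for lev in offset_levels]

    return FitDesign(
        site_index=site_index,
        Xpsi=Xpsi,
        psi_names=list(spec.psi_terms),
        y01=y01,
        obs=obs,
        no_det=no_det,
        eff_z=eff_z,
        effort_mean=e_mean,
        effort_sd=e_sd,
        survey_dummies=survey_dummies,
        survey_offset_levels=offset_levels,
        survey_reference=reference,
        stations=stations,
        station_starts=starts,
        use_effort="effort" in spec.p_terms,
        use_survey=use_survey,
        random_intercept=spec.random_station_intercept,
        param_names=names,
        transform_params=dict(cov.transform_params),
    )


# ---------------------------------------------------------------------------
# vectorized likelihood


def _unpack(theta: np.ndarray, d: FitDesign) -> dict[str, np.ndarray]:
    i = 0
    out = {}
    out["beta0"] = theta[:, i]
    i += 1
    P = d.Xpsi.shape[1]
    out["beta"] = theta[:, i : i + P]
    i += P
    if d.random_intercept:
        out["sigma"] = np.exp(np.clip(theta[:, i], -50.0, 50.0))
        i += 1
    else:
        out["sigma"] = np.zeros(theta.shape[0])
    out["gamma0"] = theta[:, i]
    i += 1
    if d.use_effort:
        out["gamma_effort"] = theta[:, i]
        i += 1
    else:
        out["gamma_effort"] = np.zeros(theta.shape[0])
    if d.use_survey:
        out["survey"] = theta[:, i:]
    return out


def _logsumexp_last(x: np.ndarray) -> np.ndarray:
    """Max-shifted logsumexp over the last axis (fewer temporaries than the
    scipy version; entries may be -inf)."""
    m = np.max(x, axis=-1)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    out = m_safe + np.log(np.exp(x - m_safe[..., None]).sum(axis=-1))
    return np.where(np.isfinite(m), out, m)


def _site_log_factors(
    theta: np.ndarray, d: FitDesign, quad: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Return (logF, logw): per-site log mixture factors at each quadrature
    node (B, S, Q) and the log quadrature weights (Q,)."""
    pars = _unpack(theta, d)
    eta_p = pars["gamma0"][:, None, None] + pars["gamma_effort"][:, None, None] * d.eff_z[None]
    if d.use_survey and d.survey_dummies is not None:
        eta_p = eta_p + (d.survey_dummies @ pars["survey"].T).T[:, :, None]
    logp = log_expit(eta_p)
    log1mp = logp - eta_p  # log(1 - sigmoid(x)) = log(sigmoid(x)) - x
    logD = ((d.y01 * logp + (1.0 - d.y01) * log1mp) * d.obs).sum(axis=2)  # (B,S)

    eta_psi = pars["beta0"][:, None] + pars["beta"] @ d.Xpsi.T  # (B,S)
    if d.random_intercept:
        x, w = quad
        alpha = math.sqrt(2.0) * pars["sigma"][:, None, None] * x  # (B,1,Q)
        eta = eta_psi[:, :, None] + alpha
        logw = np.log(w) - 0.5 * math.log(math.pi)
    else:
        eta = eta_psi[:, :, None]
        logw = np.zeros(1)
    lpsi = log_expit(eta)
    A = lpsi + logD[:, :, None]
    with np.errstate(invalid="ignore"):
        B = np.where(d.no_det[None, :, None], lpsi - eta, -np.inf)
    logF = np.logaddexp(A, B)
    return logF, logw


def _log_likelihood_draws(
    theta: np.ndarray, d: FitDesign, quad, want_pointwise: bool = True
) -> tuple[np.ndarray, np.ndarray | None]:
    """(total (B,), pointwise (B, S)). The total integrates the station
    intercept jointly over each station's site-years; the pointwise vector
    integrates it independently per site (exact for single-year stations),
    which is the per-site quantity PSIS-LOO consumes."""
    logF, logw = _site_log_factors(theta, d, quad)
    pointwise = _logsumexp_last(logF + logw) if want_pointwise else None
    if d.random_intercept:
        seg = np.add.reduceat(logF, d.station_starts, axis=1)  # (B, G, Q)
        total = _logsumexp_last(seg + logw).sum(axis=1)
    elif pointwise is not None:
        total = pointwise.sum(axis=1)
    else:
        total = _logsumexp_last(logF + logw).sum(axis=1)
    return total, pointwise


def _log_prior(theta: np.ndarray, d: FitDesign, priors: PriorSpec) -> np.ndarray:
    pars = _unpack(theta, d)
    lp = -0.5 * (pars["beta0"] / priors.intercept_scale) ** 2
    lp = lp - 0.5 * np.sum((pars["beta"] / priors.slope_scale) ** 2, axis=1)
    lp = lp - 0.5 * (pars["gamma0"] / priors.intercept_scale) ** 2
    if d.use_effort:
        lp = lp - 0.5 * (pars["gamma_effort"] / priors.slope_scale) ** 2
    if d.use_survey:
        lp = lp - 0.5 * np.sum((theta[:, -len(d.survey_offset_levels):] / priors.slope_scale) ** 2, axis=1)
    if d.random_intercept:
        j = len(d.psi_names) + 1
        log_sigma = theta[:, j]
        sigma = pars["sigma"]
        # half-normal on sigma, sampled on the log scale (Jacobian = sigma)
        lp = lp - 0.5 * (sigma / priors.sigma_scale) ** 2 + log_sigma
    return lp


# ---------------------------------------------------------------------------
# public likelihood (conditional on explicit parameter values)


def log_likelihood(
    params: OccupancyParams,
    history: DetectionHistory,
    cov: StandardizedCovariates,
    spec: ModelSpec,
) -> tuple[float, np.ndarray]:
    """Log-likelihood at a fixed parameter value.

    With a random intercept in the spec: if ``params.alpha`` is non-empty the
    likelihood is conditional on those station intercepts (absent stations
    get 0); if it is empty the intercept is marginalized over
    Normal(0, sigma_station), which at sigma = 0 reduces exactly to the
    fixed-effect likelihood. Returns the total and the per-site pointwise
    vector, in the design's (station, year) order.
    """
    d = build_design(history, cov, spec)
    theta = _params_to_theta(params, d)
    quad = hermgauss(20)
    if d.random_intercept and params.alpha:
        # conditional on given alphas: shift the psi predictor, no quadrature
        alpha = np.array([params.alpha.get(s, 0.0) for s in d.stations])
        d2 = replace(d, random_intercept=False)
        eta_shift = alpha
        Xa = np.concatenate([d.Xpsi, eta_shift[:, None]], axis=1)
        d2 = replace(
            d2,
            Xpsi=Xa,
            psi_names=d.psi_names + ["_alpha_offset"],
            param_names=d.param_names,
        )
        th = np.concatenate(
            [theta[:, : 1 + len(d.psi_names)], [[1.0]], theta[:, 2 + len(d.psi_names):]],
            axis=1,
        )
        total, pointwise = _log_likelihood_draws(th, d2, quad)
    else:
        total, pointwise = _log_likelihood_draws(theta, d, quad)
    if not np.all(np.isfinite(pointwise)):
        bad = int(np.flatnonzero(~np.isfinite(pointwise[0]))[0])
        raise FloatingPointError(
            f"non-finite likelihood at site {d.site_index[bad]}"
        )
    return float(total[0]), pointwise[0]


def _params_to_theta(params: OccupancyParams, d: FitDesign) -> np.ndarray:
    vals = [params.beta0]
    for t in d.psi_names:
        if t == "_alpha_offset":
            continue
        if t not in params.beta:
            raise SchemaError(f"params lack occupancy slope for {t!r}")
        vals.append(params.beta[t])
    if d.random_intercept:
        vals.append(np.log(params.sigma_station) if params.sigma_station > 0 else -50.0)
    vals.append(params.gamma0)
    if d.use_effort:
        vals.append(params.gamma_effort)
    for lev in d.survey_offset_levels:
        vals.append(params.survey_effects.get(lev, 0.0))
    return np.array(vals, dtype=float)[None, :]


# ---------------------------------------------------------------------------
# fitting


@dataclass
class PosteriorFit:
    """Posterior draws plus everything downstream stages need."""

    idata: "object"  # arviz.InferenceData
    draws: np.ndarray  # (n_draws_total, D) flattened walkers x kept steps
    param_names: list[str]
    spec: ModelSpec
    design: FitDesign
    n_chains: int
    n_walkers: int
    n_iter: int
    burn_fraction: float
    thin: int
    seed: int | None
    rhat: dict[str, float]
    pointwise_loglik: np.ndarray  # (n_draws_total, S)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.param_names)

    def sigma_draws(self) -> np.ndarray:
        if "log_sigma_station" in self.param_names:
            j = self.param_names.index("log_sigma_station")
            return np.exp(self.draws[:, j])
        return np.zeros(self.n_draws)

    def params_at(self, i: int) -> OccupancyParams:
        row = dict(zip(self.param_names, self.draws[i]))
        beta = {t: row[f"beta_{t}"] for t in self.design.psi_names if t != "_alpha_offset"}
        sv = {lev: row[f"survey_{lev}"] for lev in self.design.survey_offset_levels}
        return OccupancyParams(
            beta0=row["beta0"],
            beta=beta,
            sigma_station=float(np.exp(row["log_sigma_station"]))
            if "log_sigma_station" in row
            else 0.0,
            gamma0=row["gamma0"],
            gamma_effort=row.get("gamma_effort", 0.0),
            survey_effects=sv,
        )

    def plot_trace(self, path: str) -> None:
        """Trace-plot export hook (needs matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import arviz as az
        import matplotlib.pyplot as plt

        az.plot_trace(self.idata)
        plt.gcf().savefig(path, dpi=100, bbox_inches="tight")
        plt.close("all")


def fit(
    spec: ModelSpec,
    history: DetectionHistory,
    cov: StandardizedCovariates,
    n_chains: int = 4,
    n_iter: int = 40000,
    burn_fraction: float = 0.5,
    seed: int | None = 0,
    walkers_per_chain: int | None = None,
    thin: int | None = None,
    quad_points: int = 20,
    max_stored_draws: int = 4000,
    progress: bool = False,
) -> PosteriorFit:
    """Sample the posterior of an occupancy model.

    ``n_iter`` counts ensemble steps and ``burn_fraction`` of them is
    discarded, mirroring the long-chains-half-burned convention; retained
    draws are thinned to at most ``max_stored_draws`` before the pointwise
    log-likelihood matrix (needed for LOO) is evaluated. Walkers are grouped
    into ``n_chains`` chains for split-R-hat.
    """
    import arviz as az
    import emcee

    d = build_design(history, cov, spec)
    if d.n_sites == 0:
        raise ValueError("cannot fit an empty detection history")
    n_det = int((~d.no_det).sum())
    if n_det == 0 or n_det == d.n_sites:
        warnings.warn(
            "detection histories are all-zero or all-positive; occupancy and "
            "detection are weakly separable",
            stacklevel=2,
        )

    D = len(d.param_names)
    quad = hermgauss(quad_points)
    priors = spec.priors

    def log_post(theta2d: np.ndarray) -> np.ndarray:
        theta2d = np.atleast_2d(theta2d)
        ok = np.all(np.isfinite(theta2d), axis=1)
        out = np.full(theta2d.shape[0], -np.inf)
        if ok.any():
            th = theta2d[ok]
            total, _ = _log_likelihood_draws(th, d, quad, want_pointwise=False)
            out[ok] = total + _log_prior(th, d, priors)
        return out

    # MAP start for fast burn-in
    x0 = np.zeros(D)
    if d.random_intercept:
        x0[d.param_names.index("log_sigma_station")] = math.log(0.5)
    try:
        res = minimize(lambda th: -log_post(th[None])[0], x0, method="L-BFGS-B")
        if np.all(np.isfinite(res.x)):
            x0 = res.x
    except Exception:  # pragma: no cover - optimizer hiccups are non-fatal
        pass

    if walkers_per_chain is None:
        walkers_per_chain = max(4, math.ceil((2 * D + 2) / max(n_chains, 1)))
    n_walkers = max(n_chains, 1) * walkers_per_chain
    if n_walkers < 2 * D + 2:
        n_walkers = (2 * D + 2 + n_chains - 1) // n_chains * n_chains

    rng = np.random.default_rng(seed)
    init = x0[None, :] + 0.1 * rng.standard_normal((n_walkers, D))
    sampler = emcee.EnsembleSampler(n_walkers, D, log_post, vectorize=True)
    sampler.random_state = np.random.RandomState(
        None if seed is None else seed
    ).get_state()
    state = sampler.run_mcmc(init, n_iter, progress=progress, skip_initial_state_check=True)
    if not np.any(np.isfinite(state.log_prob)):
        raise RuntimeError("sampler failed: no walker reached finite posterior density")

    burn = int(n_iter * burn_fraction)
    if thin is None:
        kept = (n_iter - burn) * n_walkers
        thin = max(1, math.ceil(kept / max_stored_draws))
    chain = sampler.get_chain(discard=burn, thin=thin)  # (n_kept, W, D)
    chain = np.moveaxis(chain, 0, 1)  # (W, n_kept, D)
    flat = chain.reshape(-1, D)

    # pointwise log-likelihood per retained draw, in chunks
    S = d.n_sites
    pointwise = np.empty((flat.shape[0], S))
    step = max(1, int(2e6 // max(S * len(quad[0]), 1)))
    for a in range(0, flat.shape[0], step):
        _, pw = _log_likelihood_draws(flat[a : a + step], d, quad)
        pointwise[a : a + step] = pw
    if not np.all(np.isfinite(pointwise)):
        raise FloatingPointError("non-finite pointwise log-likelihood in posterior")

    posterior = {
        name: chain[:, :, j] for j, name in enumerate(d.param_names)
    }
    log_lik = {"obs": pointwise.reshape(chain.shape[0], chain.shape[1], S)}
    idata = az.from_dict(posterior=posterior, log_likelihood=log_lik)

    rhat_ds = az.rhat(idata) if n_walkers >= 2 and chain.shape[1] >= 4 else None
    rhat = (
        {name: float(rhat_ds[name]) for name in d.param_names}
        if rhat_ds is not None
        else {}
    )

    return PosteriorFit(
        idata=idata,
        draws=flat,
        param_names=d.param_names,
        spec=spec,
        design=d,
        n_chains=n_chains,
        n_walkers=n_walkers,
        n_iter=n_iter,
        burn_fraction=burn_fraction,
        thin=thin,
        seed=seed,
        rhat=rhat,
        pointwise_loglik=pointwise,
    )


# ---------------------------------------------------------------------------
# diagnostics & summaries


def split_rhat(samples: np.ndarray) -> float:
    """Split-R-hat of a (chains, draws) array (rank-normalized, via arviz)."""
    import arviz as az

    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("need a (chains >= 2, draws) array")
    ds = az.convert_to_dataset(samples)
    return float(az.rhat(ds).to_array().values.ravel()[0])


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    threshold: float
    passed: bool

    def failing(self) -> list[str]:
        return [
            k
            for k, v in self.rhat.items()
            if not np.isfinite(v) or v >= self.threshold
        ]


def check_convergence(fit: PosteriorFit, threshold: float = 1.05) -> ConvergenceReport:
    """Split-R-hat per parameter; passes iff all are finite and < threshold.

    A degenerate posterior (constant draws) yields non-finite R-hat and is
    flagged rather than silently passed.
    """
    if fit.n_walkers < 2:
        raise ValueError("R-hat is undefined for a single chain")
    rhat = fit.rhat
    if not rhat:
        import arviz as az

        ds = az.rhat(fit.idata)
        rhat = {k: float(ds[k]) for k in fit.param_names}
    passed = all(np.isfinite(v) and v < threshold for v in rhat.values())
    return ConvergenceReport(rhat=rhat, threshold=threshold, passed=passed)


def psi_draws(
    fit: PosteriorFit, mode: str = "integrated", quad_points: int = 20
) -> np.ndarray:
    """Per-site occupancy probability per posterior draw, (n_draws, S).

    ``integrated`` marginalizes the station intercept (E_alpha[psi]);
    ``conditional`` sets alpha = 0 (the typical-station surface).
    """
    d = fit.design
    i0 = 0
    beta0 = fit.draws[:, i0]
    P = len([t for t in d.psi_names])
    beta = fit.draws[:, 1 : 1 + P]
    eta = beta0[:, None] + beta @ d.Xpsi.T
    if mode == "conditional" or not d.random_intercept:
        from scipy.special import expit

        return expit(eta)
    if mode != "integrated":
        raise ValueError("mode must be 'integrated' or 'conditional'")
    sigma = fit.sigma_draws()
    x, w = hermgauss(quad_points)
    from scipy.special import expit

    out = np.zeros_like(eta)
    wbar = w / math.sqrt(math.pi)
    for q in range(len(x)):
        out += wbar[q] * expit(eta + math.sqrt(2.0) * sigma[:, None] * x[q])
    return out


def p_draws(fit: PosteriorFit) -> np.ndarray:
    """Per-draw detection probability averaged over observed site-occasions."""
    from scipy.special import expit

    d = fit.design
    names = fit.param_names
    g0 = fit.draws[:, names.index("gamma0")]
    ge = (
        fit.draws[:, names.index("gamma_effort")]
        if "gamma_effort" in names
        else np.zeros(fit.n_draws)
    )
    out = np.zeros(fit.n_draws)
    sv_offsets = np.zeros(d.n_sites)
    chunk = max(1, int(5e6 // max(d.n_sites * d.y01.shape[1], 1)))
    for a in range(0, fit.n_draws, chunk):
        g0c = g0[a : a + chunk, None, None]
        gec = ge[a : a + chunk, None, None]
        eta = g0c + gec * d.eff_z[None]
        if d.use_survey and d.survey_dummies is not None:
            sv = fit.draws[a : a + chunk, -len(d.survey_offset_levels):]
            eta = eta + (d.survey_dummies @ sv.T).T[:, :, None]
        p = expit(eta)
        out[a : a + chunk] = p[:, d.obs].mean(axis=1)
    return out


@dataclass
class PosteriorSummary:
    """Posterior mean, SD and central 95% interval per parameter, plus the
    derived site-mean habitat use (psi_bar) and occasion-mean detection
    (p_bar) over the observed design."""

    table: pd.DataFrame

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]


def summarize(fit: PosteriorFit, ci: float = 0.95) -> PosteriorSummary:
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2

    def _row(x: np.ndarray) -> dict:
        return {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "ci_lo": float(np.percentile(x, lo_q)),
            "ci_hi": float(np.percentile(x, hi_q)),
        }

    rows = {}
    for j, name in enumerate(fit.param_names):
        if name == "log_sigma_station":
            rows["sigma_station"] = _row(np.exp(fit.draws[:, j]))
        else:
            rows[name] = _row(fit.draws[:, j])
    psi = psi_draws(fit, mode="integrated")
    rows["psi_bar"] = _row(psi.mean(axis=1))
    rows["p_bar"] = _row(p_draws(fit))
    table = pd.DataFrame(rows).T[["mean", "sd", "ci_lo", "ci_hi"]]
    bad = table[table["ci_lo"] > table["ci_hi"]]
    assert bad.empty
    return PosteriorSummary(table=table)
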