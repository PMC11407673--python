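"""Model ranking by PSIS-LOO elpd, model weights, and backward elimination.

Candidate models are compared on expected log pointwise predictive density
estimated by Pareto-smoothed importance-sampling leave-one-out
cross-validation (PSIS-LOO) over the per-site pointwise log-likelihoods.
Weights default to Bayesian-bootstrap pseudo-BMA, which regularizes by the
pointwise variance; stacking is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import SITE_COVARIATES, StandardizedCovariates
from .history import DetectionHistory
from .model import ModelSpec, PosteriorFit, fit as fit_model, summarize

ENVIRONMENTAL_TERMS = ["tree_cover", "dist_water", "elevation", "ruggedness"]
ANTHROPOGENIC_TERMS = ["dist_settlement", "dist_road"]


@dataclass
class LooResult:
    """PSIS-LOO decomposition for one fitted model."""

    elpd_i: np.ndarray  # per-site elpd
    elpd: float
    se: float
    pareto_k: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.elpd_i.size


def pointwise_elpd_loo(fit: PosteriorFit, k_threshold: float = 0.7) -> LooResult:
    """PSIS-LOO from the fit's pointwise log-likelihood matrix.

    Warns with the offending site indices when any Pareto k exceeds
    ``k_threshold`` (the importance weights for those sites are unreliable).
    """
    import arviz as az

    res = az.loo(fit.idata, pointwise=True)
    elpd_i = np.asarray(res.loo_i.values, dtype=float)
    k = np.asarray(res.pareto_k.values, dtype=float)
    bad = np.flatnonzero(k > k_threshold)
    if bad.size:
        warnings.warn(
            f"PSIS-LOO Pareto k > {k_threshold} at sites {bad.tolist()}",
            stacklevel=2,
        )
    return LooResult(
        elpd_i=elpd_i,
        elpd=float(res.elpd_loo),
        se=float(res.se),
        pareto_k=k,
    )


@dataclass
class ModelComparison:
    """Ranked comparison table (columns: model, elpd, elpd_se, delta_elpd,
    weight), sorted by decreasing elpd; delta of the best model is 0 and the
    others are negative, the printed-table convention."""

    table: pd.DataFrame
    best: str

    def __post_init__(self) -> None:
        w = self.table["weight"].to_numpy()
        assert np.all(w >= -1e-12) and abs(w.sum() - 1.0) < 1e-9


def compare_models(
    fits: dict[str, PosteriorFit],
    method: str = "BB-pseudo-BMA",
    seed: int = 0,
) -> ModelComparison:
    """Rank labeled fits by PSIS-LOO elpd with pseudo-BMA (default) or
    stacking weights. All fits must share the same site set."""
    if not fits:
        raise ValueError("no fits to compare")
    labels = list(fits)
    ref = fits[labels[0]].design.site_index
    for lab in labels[1:]:
        if fits[lab].design.site_index != ref:
            raise ValueError(f"fit {lab!r} is on a different site set")

    if len(labels) == 1:
        loo = pointwise_elpd_loo(fits[labels[0]])
        table = pd.DataFrame(
            {
                "model": labels,
                "elpd": [loo.elpd],
                "elpd_se": [loo.se],
                "delta_elpd": [0.0],
                "weight": [1.0],
            }
        )
        return ModelComparison(table=table, best=labels[0])

    import arviz as az

    cmp = az.compare(
        {lab: f.idata for lab, f in fits.items()},
        ic="loo",
        method=method,
        seed=seed,
    )
    cmp = cmp.sort_values("elpd_loo", ascending=False)
    best = str(cmp.index[0])
    best_elpd = float(cmp["elpd_loo"].iloc[0])
    table = pd.DataFrame(
        {
            "model": cmp.index,
            "elpd": cmp["elpd_loo"].to_numpy(float),
            "elpd_se": cmp["se"].to_numpy(float),
            "delta_elpd": cmp["elpd_loo"].to_numpy(float) - best_elpd,
            "weight": cmp["weight"].to_numpy(float),
        }
    ).reset_index(drop=True)
    return ModelComparison(table=table, best=best)


@dataclass
class EliminationStep:
    removed: str
    elpd_before: float
    elpd_after: float
    accepted: bool


def backward_eliminate(
    start_spec: ModelSpec,
    history: DetectionHistory,
    cov: StandardizedCovariates,
    fit_kwargs: dict | None = None,
    margin: float = 0.0,
    seed: int = 0,
) -> tuple[ModelSpec, list[EliminationStep]]:
    """Drop the weakest occupancy term (smallest |posterior mean| / sd) one
    at a time, keeping a removal whenever elpd does not fall by more than
    ``margin``; stops at the first rejected removal or when no terms remain.
    """
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("seed", seed)
    trail: list[EliminationStep] = []
    current = start_spec
    if not current.psi_terms:
        return current, trail
    cur_fit = fit_model(current, history, cov, **fit_kwargs)
    cur_elpd = pointwise_elpd_loo(cur_fit).elpd
    while current.psi_terms:
        summ = summarize(cur_fit).table
        scores = {}
        for t in current.psi_terms:
            row = summ.loc[f"beta_{t}"]
            scores[t] = abs(row["mean"]) / max(row["sd"], 1e-12)
        weakest = min(scores, key=scores.get)
        candidate = current.without(weakest)
        cand_fit = fit_model(candidate, history, cov, **fit_kwargs)
        cand_elpd = pointwise_elpd_loo(cand_fit).elpd
        accepted = cand_elpd >= cur_elpd - margin
        trail.append(
            EliminationStep(
                removed=weakest,
                elpd_before=cur_elpd,
                elpd_after=cand_elpd,
                accepted=accepted,
            )
        )
        if not accepted:
            break
        current, cur_fit, cur_elpd = candidate, cand_fit, cand_elpd
    return current, trail


def build_candidate_set(
    psi_covariates: list[str] | None = None,
    environmental: list[str] | None = None,
    anthropogenic: list[str] | None = None,
    include_survey: bool = True,
) -> dict[str, ModelSpec]:
    """The named hypothesis set: a null model, a Year-trend null, the global
    model with and without the station random intercept, an
    environmental-only model and an anthropogenic-only model. Every model
    except the pure null carries effort on detection; the globals also carry
    the survey factor."""
    psi_covariates = list(psi_covariates or SITE_COVARIATES)
    environmental = list(environmental or ENVIRONMENTAL_TERMS)
    anthropogenic = list(anthropogenic or ANTHROPOGENIC_TERMS)
    global_p = ["effort", "survey"] if include_survey else ["effort"]
    specs = {
        "null": ModelSpec(psi_terms=[], p_terms=[], label="P(.)psi(.)"),
        "null_year": ModelSpec(
            psi_terms=["year"], p_terms=["effort"], label="P(effort)psi(year)"
        ),
        "global_random": ModelSpec(
            psi_terms=psi_covariates,
            p_terms=global_p,
            random_station_intercept=True,
            label="P(effort+survey)psi(global)+RI",
        ),
        "global_fixed": ModelSpec(
            psi_terms=psi_covariates,
            p_terms=global_p,
            label="P(effort+survey)psi(global)",
        ),
        "environmental": ModelSpec(
            psi_terms=environmental,
            p_terms=["effort"],
            random_station_intercept=True,
            label="P(effort)psi(tc+water+elev+tri)+RI",
        ),
        "anthropogenic": ModelSpec(
            psi_terms=anthropogenic,
            p_terms=["effort"],
            random_station_intercept=True,
            label="P(effort)psi(set+road)+RI",
        ),
    }
    return specs
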