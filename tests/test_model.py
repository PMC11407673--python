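"""Occupancy likelihood correctness (against exhaustive latent-state
enumeration), prior/posterior machinery, convergence diagnostics, and
posterior summaries."""

import dataclasses
import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import camtrap_occupancy as co
from camtrap_occupancy.model import SchemaError, split_rhat


def make_history(y, effort, stations=None, years=None):
    y = np.asarray(y, dtype=float)
    effort = np.asarray(effort, dtype=float)
    n = y.shape[0]
    stations = stations or [f"S{i}" for i in range(n)]
    years = years or [2020] * n
    hist = co.DetectionHistory(
        site_index=list(zip(stations, years)), y=y, effort=effort
    )
    hist.validate()
    return hist


def make_cov(stations, years=None, survey="OC"):
    n = len(stations)
    return co.StandardizedCovariates(
        data=pd.DataFrame(
            {
                "station_id": stations,
                "year": years or [2020] * n,
                "survey": [survey] * n,
            }
        ),
        transform_params={},
    )


class TestSiteMarginalLikelihood:
    def test_certainty(self):
        assert co.site_marginal_likelihood(1.0, [1.0, 1.0], [1, 1]) == 1.0

    def test_all_zero_mixture(self):
        assert co.site_marginal_likelihood(0.5, [0.5, 0.5], [0, 0]) == pytest.approx(
            0.625, abs=1e-15
        )

    def test_missing_occasion_contributes_no_factor(self):
        assert co.site_marginal_likelihood(
            0.5, [0.5, 0.5], [1, float("nan")]
        ) == pytest.approx(0.25, abs=1e-15)

    @pytest.mark.parametrize("K", [1, 2, 3, 4])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_normalization_over_all_histories(self, K, seed):
        rng = np.random.default_rng(seed)
        psi = rng.uniform(0.05, 0.95)
        p = rng.uniform(0.05, 0.95, size=K)
        total = sum(
            co.site_marginal_likelihood(psi, p, list(y))
            for y in product([0, 1], repeat=K)
        )
        assert total == pytest.approx(1.0, abs=1e-10)


def enumeration_loglik(psi, p, y):
    """Independent oracle: sum the joint probability of the observed data
    over every latent presence configuration (2^S states)."""
    S = len(psi)
    total = 0.0
    for zvec in product([0, 1], repeat=S):
        prob = 1.0
        for i, z in enumerate(zvec):
            prob *= psi[i] if z else 1.0 - psi[i]
            for t in range(len(y[i])):
                yt = y[i][t]
                if math.isnan(yt):
                    continue
                pe = p[i][t] if z else 0.0
                prob *= pe if yt == 1 else 1.0 - pe
        total += prob
    return math.log(total)


class TestLogLikelihood:
    def test_hand_value_two_zero_occasions(self):
        hist = make_history([[0.0, 0.0]], [[15.0, 15.0]])
        cov = make_cov(["S0"])
        spec = co.ModelSpec(psi_terms=[], p_terms=[])
        total, pointwise = co.log_likelihood(co.OccupancyParams(), hist, cov, spec)
        assert total == pytest.approx(math.log(0.625), abs=1e-12)
        assert pointwise.shape == (1,)

    def test_single_observed_occasion_reduces_to_k1_mixture(self):
        hist = make_history([[np.nan, 1.0, np.nan]], [[0.0, 10.0, 0.0]])
        cov = make_cov(["S0"])
        params = co.OccupancyParams(beta0=0.3, gamma0=-0.4)
        total, _ = co.log_likelihood(
            params, hist, cov, co.ModelSpec(psi_terms=[], p_terms=[])
        )
        expected = math.log(expit(0.3) * expit(-0.4))
        assert total == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_latent_state_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        S = int(rng.integers(1, 4))
        K = int(rng.integers(1, 4))
        effort = np.where(rng.random((S, K)) < 0.25, 0.0, 15.0)
        for i in range(S):
            if (effort[i] == 0).all():
                effort[i, rng.integers(0, K)] = 15.0
        y = np.where(effort > 0, rng.binomial(1, 0.4, size=(S, K)), np.nan).astype(float)
        alphas = rng.normal(0, 1, size=S)
        beta0 = float(rng.normal(0, 1))
        gamma0 = float(rng.normal(0, 1))
        stations = [f"S{i}" for i in range(S)]
        hist = make_history(y, effort, stations=stations)
        cov = make_cov(stations)
        spec = co.ModelSpec(psi_terms=[], p_terms=[], random_station_intercept=True)
        params = co.OccupancyParams(
            beta0=beta0,
            gamma0=gamma0,
            sigma_station=1.0,
            alpha={s: a for s, a in zip(stations, alphas)},
        )
        total, pointwise = co.log_likelihood(params, hist, cov, spec)
        psi = [float(expit(beta0 + a)) for a in alphas]
        p = [[float(expit(gamma0))] * K for _ in range(S)]
        assert total == pytest.approx(enumeration_loglik(psi, p, y.tolist()), abs=1e-10)
        assert total == pytest.approx(float(pointwise.sum()), abs=1e-10)

    def test_matches_enumeration_with_effort_slope(self):
        rng = np.random.default_rng(42)
        S, K = 3, 3
        effort = rng.integers(1, 16, size=(S, K)).astype(float)
        y = rng.binomial(1, 0.5, size=(S, K)).astype(float)
        stations = [f"S{i}" for i in range(S)]
        hist = make_history(y, effort, stations=stations)
        cov = make_cov(stations)
        spec = co.ModelSpec(psi_terms=[], p_terms=["effort"])
        params = co.OccupancyParams(beta0=-0.2, gamma0=-0.5, gamma_effort=0.7)
        total, _ = co.log_likelihood(params, hist, cov, spec)
        ez = (effort - effort.mean()) / effort.std(ddof=1)
        psi = [float(expit(-0.2))] * S
        p = expit(-0.5 + 0.7 * ez)
        assert total == pytest.approx(
            enumeration_loglik(psi, p.tolist(), y.tolist()), abs=1e-10
        )

    def test_sigma_zero_equals_fixed_effect_likelihood(self):
        hist = make_history(
            [[1.0, 0.0], [0.0, 0.0]], [[15.0, 15.0], [15.0, 10.0]]
        )
        cov = make_cov(["S0", "S1"])
        params = co.OccupancyParams(beta0=0.4, gamma0=-1.0, sigma_station=0.0)
        spec_ri = co.ModelSpec(psi_terms=[], p_terms=[], random_station_intercept=True)
        spec_fe = co.ModelSpec(psi_terms=[], p_terms=[])
        t_ri, _ = co.log_likelihood(params, hist, cov, spec_ri)
        t_fe, _ = co.log_likelihood(params, hist, cov, spec_fe)
        assert t_ri == pytest.approx(t_fe, abs=1e-12)

    def test_missing_term_is_schema_error(self):
        hist = make_history([[0.0]], [[15.0]])
        cov = make_cov(["S0"])
        with pytest.raises(SchemaError):
            co.log_likelihood(
                co.OccupancyParams(beta={"tree_cover": 1.0}, beta0=0.0),
                hist,
                cov,
                co.ModelSpec(psi_terms=["tree_cover"], p_terms=[]),
            )


class TestFitAndDiagnostics:
    def test_recovers_generating_slope_within_posterior_uncertainty(self, small_fit, small_study):
        cfg, *_ = small_study
        _, fit = small_fit
        summ = co.summarize(fit).table
        row = summ.loc["beta_tree_cover"]
        true = cfg.true_params.beta["tree_cover"]
        assert abs(row["mean"] - true) < 3 * row["sd"]

    def test_convergence_report_on_real_fit(self, small_fit):
        _, fit = small_fit
        report = co.check_convergence(fit, threshold=1.2)
        assert set(report.rhat) == set(fit.param_names)
        assert all(np.isfinite(v) for v in report.rhat.values())

    def test_single_chain_rhat_is_error(self, small_fit):
        _, fit = small_fit
        broken = dataclasses.replace(fit, n_walkers=1)
        with pytest.raises(ValueError):
            co.check_convergence(broken)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.normal(0, 0.1, 500), rng.normal(10, 0.1, 500)])
        assert split_rhat(chains) > 1.5

    def test_constant_chains_degenerate(self):
        chains = np.ones((2, 500))
        r = split_rhat(chains)
        assert not np.isfinite(r) or r > 1.05

    def test_summary_of_constant_draws_collapses(self, small_fit):
        _, fit = small_fit
        frozen = dataclasses.replace(
            fit, draws=np.repeat(fit.draws[:1], 50, axis=0)
        )
        summ = co.summarize(frozen).table
        assert (summ["sd"] < 1e-12).all()
        np.testing.assert_allclose(summ["ci_lo"], summ["mean"], atol=1e-12)
        np.testing.assert_allclose(summ["ci_hi"], summ["mean"], atol=1e-12)

    def test_summary_intervals_are_ordered_and_probabilities_bounded(self, small_fit):
        _, fit = small_fit
        summ = co.summarize(fit).table
        assert (summ["ci_lo"] <= summ["mean"] + 1e-12).all()
        assert (summ["mean"] <= summ["ci_hi"] + 1e-12).all()
        for name in ("psi_bar", "p_bar"):
            assert 0 <= summ.loc[name, "ci_lo"] <= summ.loc[name, "ci_hi"] <= 1
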