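import warnings
from types import SimpleNamespace

import numpy as np
import pytest

import camtrap_occupancy as co

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture(scope="session")
def small_study():
    """A modest stacked study reused across test modules: 60 stations x 2
    years, 5 occasions, moderate detection rates."""
    cfg = co.SimulationConfig(
        n_stations=60,
        years_per_station=2,
        n_occasions=5,
        deploy_days_min=60,
        deploy_days_max=75,
        seed=11,
    )
    cov = co.simulate_covariates(cfg)
    hist, latent = co.simulate_detection_history(cov, cfg)
    covz = co.z_transform(cov)
    return cfg, cov, covz, hist, latent


@pytest.fixture(scope="session")
def small_fit(small_study):
    """One fitted single-covariate model shared by selection/gof/spatial tests."""
    _, _, covz, hist, _ = small_study
    spec = co.ModelSpec(psi_terms=["tree_cover"], p_terms=["effort"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = co.fit(spec, hist, covz, n_iter=1500, seed=3, quad_points=15)
    return spec, fit


def make_fake_fit(param_names, draws, pointwise, site_index=None, psi_names=None):
    """A minimal PosteriorFit stand-in (synthetic draws, no sampler run) for
    operations that only consume draws and pointwise log-likelihoods."""
    import arviz as az

    draws = np.asarray(draws, dtype=float)
    pointwise = np.asarray(pointwise, dtype=float)
    n, s = pointwise.shape
    posterior = {name: draws[None, :, j] for j, name in enumerate(param_names)}
    idata = az.from_dict(
        posterior=posterior, log_likelihood={"obs": pointwise[None]}
    )
    design = SimpleNamespace(
        site_index=site_index or [(f"S{i}", 0) for i in range(s)],
        psi_names=psi_names or [],
        transform_params={},
        random_intercept="log_sigma_station" in param_names,
        n_sites=s,
    )
    return co.PosteriorFit(
        idata=idata,
        draws=draws,
        param_names=list(param_names),
        spec=co.ModelSpec(psi_terms=list(psi_names or [])),
        design=design,
        n_chains=1,
        n_walkers=1,
        n_iter=n,
        burn_fraction=0.0,
        thin=1,
        seed=0,
        rhat={},
        pointwise_loglik=pointwise,
    )
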