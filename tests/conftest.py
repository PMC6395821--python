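import numpy as np
import pandas as pd
import pytest

import thermoselect as ts
from thermoselect.rsf import ModelSpec


@pytest.fixture(scope="session")
def small_stack():
    """A 60x60 valley used by most spatial tests."""
    return ts.generate_landscape(ts.LandscapeConfig(nrows=60, ncols=60, seed=5))


@pytest.fixture(scope="session")
def weather60():
    return ts.generate_weather(ts.WeatherConfig(n_days=60, seed=6))


@pytest.fixture(scope="session")
def gaussian_pixels():
    """An abstract pixel pool with four independent standard-normal covariates."""
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        {
            "a": rng.normal(0, 1, 4000),
            "b": rng.normal(0, 1, 4000),
            "t": rng.normal(0, 1, 4000),
            "noise": rng.normal(0, 1, 4000),
        }
    )


@pytest.fixture(scope="session")
def recovery_truth():
    """Ground truth for parameter-recovery checks: three linear effects
    plus a concave temperature response."""
    spec = ModelSpec((("a",), ("b",), ("t",), ("t", "t")), temperature=None)
    return ts.TrueRSF(spec, np.array([0.8, -0.5, 0.3, -0.4]))


@pytest.fixture(scope="session")
def fitted_chain(small_stack, weather60):
    """One full small-world chain: observations -> design -> fit."""
    truth_spec = ModelSpec(
        (("temp",), ("temp", "temp"), ("ndvi",), ("slope",)), temperature="max_daily"
    )
    truth = ts.TrueRSF(truth_spec, [0.8, -0.4, 0.5, -0.3])
    thermal_truth = ts.ThermalTruth(sector_offsets=np.zeros(3))
    obs = ts.simulate_observations(
        small_stack, weather60, truth, thermal_truth,
        n_individuals=40, n_days=40, seed=7,
    )
    net = ts.generate_logger_data(small_stack, weather60, noise_sd=0.3, n_loggers=12, seed=9)
    thermal = ts.fit_thermal_model(net, weather60)
    domain = ts.availability_domain(obs, "large")
    table = ts.sample_available(obs, domain, 10, small_stack, seed=8)
    table = ts.attach_covariates(table, small_stack, thermal, weather60)
    table, scaling = ts.standardize(table)
    fit = ts.RSFModel(table, truth_spec, scaling).fit()
    return {
        "truth": truth,
        "obs": obs,
        "thermal": thermal,
        "domain": domain,
        "table": table,
        "scaling": scaling,
        "fit": fit,
        "spec": truth_spec,
    }
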