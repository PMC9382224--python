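import numpy as np
import pytest

from ftleforage.synthetic import (
    FlowSpec,
    WhaleSimSpec,
    gen_analytic_field,
    gen_random_ftle_series,
    simulate_whale_deployments,
)


@pytest.fixture(scope="session")
def uniform_field():
    spec = FlowSpec(kind="uniform", params={"u0": 0.1, "v0": 0.0},
                    domain=(0, 400, 0, 200), grid_spacing_km=10,
                    duration_hours=52)
    return spec, gen_analytic_field(spec)


@pytest.fixture(scope="session")
def saddle_field():
    spec = FlowSpec(kind="saddle", params={"a": 0.5}, domain=(0, 200, 0, 100),
                    grid_spacing_km=10, duration_hours=52)
    return spec, gen_analytic_field(spec)


@pytest.fixture(scope="session")
def double_gyre_spec():
    return FlowSpec(kind="double_gyre",
                    params={"A": 0.1, "eps": 0.25, "omega": 2 * np.pi / 24},
                    domain=(0, 200, 0, 100), grid_spacing_km=5.0,
                    duration_hours=52, step_hours=1.0)


@pytest.fixture(scope="session")
def random_ftle_series():
    x = np.linspace(-123.5, -121.5, 41)
    y = np.linspace(35.0, 37.0, 41)
    times = (np.datetime64("2017-09-01T00")
             + np.arange(0, 24 * 14).astype("timedelta64[h]"))
    return gen_random_ftle_series(x, y, times, corr_time_hours=6.0, seed=11,
                                  geographic=True)


@pytest.fixture(scope="session")
def simulated_deployments(random_ftle_series):
    spec = WhaleSimSpec(n_individuals=4, duration_days=4.0, seed=21)
    return simulate_whale_deployments(spec, random_ftle_series)
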