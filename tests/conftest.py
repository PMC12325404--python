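import numpy as np
import pytest

from truthfx import (
    DesignSpec,
    McmcSettings,
    fit_model,
    simulate_dataset,
    toy_trials,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_table():
    return toy_trials()


def tiny_settings(seed: int, **overrides) -> McmcSettings:
    """Fast MCMC profile for unit tests (not for inference quality)."""
    defaults = dict(chains=2, warmup=250, draws=600, max_leapfrog=16)
    defaults.update(overrides)
    return McmcSettings(seed=seed, **defaults)


@pytest.fixture(scope="session")
def small_m1_fit():
    """M1 fit to a small M1-generated table, reused across tests."""
    design = DesignSpec(n_statements=20, n_participants=60, sigma_u=0.3, sigma_v=0.05, seed=81)
    trials, params = simulate_dataset(design, 1, 0.3)
    fit = fit_model(trials, 1, settings=tiny_settings(17, draws=800))
    return trials, params, fit


@pytest.fixture(scope="session")
def m2_data_and_fits():
    """M1 and M2 both fitted to the same M2-generated table (m large)."""
    design = DesignSpec(
        n_statements=30, n_participants=120, sigma_u=0.3, sigma_v=0.05,
        plausibility_source="grid_uniform", seed=93,
    )
    trials, _ = simulate_dataset(design, 2, 0.4)
    fits = {v: fit_model(trials, v, settings=tiny_settings(200 + v, draws=800)) for v in (1, 2)}
    return trials, fits
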