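import numpy as np
import pytest

from rootnirs import (
    CVProtocol,
    ScatterSpec,
    SimulationConfig,
    simulate_spectra,
    simulate_traits,
)


def variance_components(**overrides) -> dict:
    """Per-trait variance maps with every component zero unless overridden."""
    base = dict(sigma2_g=0.0, sigma2_r=0.0, sigma2_k=0.0, sigma2_ge=0.0, sigma2_e=0.0)
    base.update(overrides)
    return {"StC": dict(base), "DMCo": dict(base)}


@pytest.fixture
def quiet_config() -> SimulationConfig:
    """Small noise-free configuration: 12 clones, one env, deterministic."""
    return SimulationConfig(
        n_clones=12,
        n_envs=1,
        n_reps=2,
        n_blocks_per_rep=1,
        variance_components=variance_components(),
        env_effect_sd=0.0,
        dmcg_noise_sd=0.0,
        baseline_amplitude=0.0,
        scatter={"fresh": ScatterSpec(0, 0, 0), "mashed": ScatterSpec(0, 0, 0)},
        noise_sd={"fresh": 0.0, "mashed": 0.0},
        readings_per_plot={"fresh": 3, "mashed": 2},
        fresh_trait_jitter_sd=0.0,
        fresh_plot_bias_sd=0.0,
        seed=7,
    )


@pytest.fixture
def small_study():
    """A modest noisy study used across calibration tests: 60 clones, one
    environment, two reps, mashed spectra aggregated to plot level."""
    from rootnirs.calibrate import aggregate_readings, trait_vector

    cfg = SimulationConfig(n_clones=60, n_envs=1, n_reps=2, seed=21)
    traits = simulate_traits(cfg)
    ds = simulate_spectra(traits, "mashed", cfg)
    plot_ids, X = aggregate_readings(ds)
    y = trait_vector(traits, plot_ids, "DMCo")
    return dict(config=cfg, traits=traits, ds=ds, plot_ids=plot_ids, X=X, y=y)


@pytest.fixture
def protocol() -> CVProtocol:
    return CVProtocol(seed=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
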