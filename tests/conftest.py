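import numpy as np
import pytest

import troposcale as ts


@pytest.fixture(scope="session")
def line():
    """Posterior-median discrimination line from the fish meta-analysis."""
    return ts.DiscriminationLine(beta0=5.92, beta1=-0.27)


@pytest.fixture(scope="session")
def params(line):
    return ts.derive_scaled_params(line)


@pytest.fixture(scope="session")
def sa_base():
    """South-Africa-like zooplankton baseline: 5.2 ‰ at TL2."""
    return ts.BaselineSpec(baseline_delta15N=5.2, baseline_tl=2)


@pytest.fixture(scope="session")
def arctic_base():
    """Arctic-like zooplankton baseline: 10.2 ‰ at TL2."""
    return ts.BaselineSpec(baseline_delta15N=10.2, baseline_tl=2)


@pytest.fixture(scope="session")
def sim_observations():
    """59 synthetic feeding studies at the meta-analysis conditions."""
    obs, truth = ts.simulate_experiments(ts.ExperimentSimConfig(seed=42))
    return obs, truth


@pytest.fixture(scope="session")
def short_fit(sim_observations):
    """One short-run posterior fit shared across tests (expensive)."""
    obs, _ = sim_observations
    return ts.fit_meta_model(obs, mcmc_config=ts.McmcConfig.short(seed=7))


@pytest.fixture(scope="session")
def zero_noise_web(line):
    """Noise-free synthetic food web on the scaled curve, known TPs 3..6."""
    cfg = ts.FoodwebSimConfig(
        species_tp={
            "planktivore_a": ("zooplanktivore", 3.0),
            "piscivore_b": ("primary_piscivore", 4.0),
            "piscivore_c": ("secondary_piscivore", 5.0),
            "apex_d": ("tertiary_piscivore", 6.0),
        },
        n_per_species=5,
        individual_sd=0.0,
        baseline_sd=0.0,
        line=line,
        seed=1,
    )
    return ts.simulate_foodweb(cfg), cfg
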