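"""Shared fixtures: one default synthetic study per session plus small helpers."""
import numpy as np
import pytest

from seedfit.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def default_study():
    """Full default-condition synthetic study (182 adults, 588 seeds)."""
    cfg = SimConfig(rng_seed=1)
    adults, seedlings, phen, truth = simulate_all(cfg)
    return {"cfg": cfg, "adults": adults, "seedlings": seedlings,
            "phen": phen, "truth": truth}


@pytest.fixture(scope="session")
def small_study():
    """Reduced cohort for cheaper end-to-end style tests."""
    cfg = SimConfig(rng_seed=3, n_adults=60, n_mothers=3, seeds_per_mother=40,
                    n_censuses=12)
    adults, seedlings, phen, truth = simulate_all(cfg)
    return {"cfg": cfg, "adults": adults, "seedlings": seedlings,
            "phen": phen, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
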