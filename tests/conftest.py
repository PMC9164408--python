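import numpy as np
import pandas as pd
import pytest

import dlqivalue as dv


@pytest.fixture(scope="session")
def catalogue():
    return dv.build_catalogue(dv.generate_orthogonal_core(64, rng_seed=1))


@pytest.fixture(scope="session")
def blocks(catalogue):
    return dv.assign_blocks(catalogue, 18, rng_seed=2)


@pytest.fixture(scope="session")
def final_design():
    """The 13-dummy support of the published final model."""
    return dv.DummyDesign.full().subset(list(dv.reference.FINAL_DUMMIES))


@pytest.fixture(scope="session")
def trader_cohort(catalogue, blocks):
    """Pure trader cohort (no contamination), n = 500."""
    params = dv.SimulationParams(rng_seed=11, p_careless=0.0,
                                 p_nontrader_base=-30.0, p_nontrader_slope=0.0)
    return dv.simulate_cohort(catalogue, blocks, 500, params), params


@pytest.fixture(scope="session")
def mixed_cohort(catalogue, blocks):
    """Full mixture cohort at study scale (traders + non-traders + careless)."""
    params = dv.SimulationParams(rng_seed=7)
    return dv.simulate_cohort(catalogue, blocks, 2001, params), params


@pytest.fixture(scope="session")
def screened(mixed_cohort):
    ds, _ = mixed_cohort
    outcome, traders = dv.screen_sample(ds)
    return outcome, traders
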