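"""Shared fixtures: one synthetic campaign and one noiseless batch, reused
session-wide because the simulator is the expensive part of the suite."""

from __future__ import annotations

import numpy as np
import pytest

from mbrkit.design import expand_design, load_design_table
from mbrkit.simulate import KineticParams, generate_campaign, simulate_batch_phase

CAMPAIGN_SEED = 1


@pytest.fixture(scope="session")
def design_table():
    return load_design_table()


@pytest.fixture(scope="session")
def params():
    return KineticParams()


@pytest.fixture(scope="session")
def campaign(design_table):
    """Default 48-run campaign with measurement noise and the failure run."""
    return generate_campaign(design_table, seed=CAMPAIGN_SEED)


@pytest.fixture(scope="session")
def noiseless_campaign(design_table):
    """One replicate per condition, noise off, no failure run."""
    return generate_campaign(
        design_table, KineticParams().noiseless(), seed=0, replicates=1,
        failure_run=None,
    )


@pytest.fixture(scope="session")
def batch20(design_table, params):
    """Noiseless unfed batch at S0 = 20 g/L (no hunger)."""
    plans = expand_design(design_table)
    plan = next(p for p in plans
                if p.condition.S0 == 20 and p.condition.hunger_h == 0)
    return simulate_batch_phase(plan, params)


@pytest.fixture()
def rng():
    """Fresh seeded generator per test, so tests stay order-independent."""
    return np.random.default_rng(1234)
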