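"""Shared fixtures: cell parameters and the Monte-Carlo ensembles reused
across the observable-trend, convergence and inhibition tests.

Chain budgets are desk-scale (2e4–6e4 production steps); the assertions they
feed are tolerance-based trends, far above the resulting Monte-Carlo error.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large])
settings.load_profile("suite")

from homeostat import CellParameters, elastic, island, with_suspension
from homeostat.sampler import sample_homeostatic_ensemble

STIFFNESS_STEPS = {1.0: 20_000, 3.0: 30_000, 10.0: 30_000,
                   30.0: 30_000, 70.0: 60_000}
ISLAND_AREAS = (8100.0, 11025.0)
ROCK_AREA = 2725.0


@pytest.fixture(scope="session")
def params0():
    return with_suspension(CellParameters())


@pytest.fixture(scope="session")
def stiffness_ensembles(params0):
    """One homeostatic ensemble per substrate stiffness (kPa)."""
    out = {}
    for E, n in STIFFNESS_STEPS.items():
        out[E] = sample_homeostatic_ensemble(
            elastic(E), params0, seed=101 + int(E),
            production_steps=n, pilot_steps=2500)
    return out


@pytest.fixture(scope="session")
def island_ensembles(params0):
    """Large-island ensembles for the spreading-convergence comparison."""
    return {a: sample_homeostatic_ensemble(
        island(a), params0, seed=211, production_steps=60_000,
        pilot_steps=2500) for a in ISLAND_AREAS}


@pytest.fixture(scope="session")
def rock_pair(params0):
    """Paired untreated / ROCK-inhibited ensembles on a 2725 µm² island.

    Both arms share one seed so the contrast is not polluted by independent
    ζ-solve noise.
    """
    treated_params = with_suspension(CellParameters(sigma_max=231.0))
    kw = dict(production_steps=40_000, pilot_steps=2500)
    untreated = sample_homeostatic_ensemble(island(ROCK_AREA), params0,
                                            seed=77, **kw)
    treated = sample_homeostatic_ensemble(island(ROCK_AREA), treated_params,
                                          seed=77, **kw)
    return untreated, treated
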