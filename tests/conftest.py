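import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_space_4():
    """All 256 4-site sequences."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=4)]


@pytest.fixture(scope="session")
def multiplicative_landscape(toy_space_4):
    """A strictly multiplicative fitness landscape on the 4^4 toy space."""
    rng = np.random.default_rng(11)
    ref = "ACGT"
    effects = {(i, b): rng.uniform(0.2, 1.6) for i in range(4) for b in "ACGT"}
    fit = {}
    for g in toy_space_4:
        w = 1.0
        for i, b in enumerate(g):
            if b != ref[i]:
                w *= effects[(i, b)]
        fit[g] = w
    return ref, pd.Series(fit)


@pytest.fixture(scope="session")
def small_experiment():
    """A quick full simulated experiment (reduced depth), both temperatures."""
    from helixscape.synthetic_data import SimConfig, simulate_experiment

    cfg = SimConfig(seed=5, depth=200_000)
    return simulate_experiment(cfg, temperatures=("30C", "37C"))
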