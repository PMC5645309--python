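import numpy as np
import pytest

from fourcmap.pipeline import build_scenario, run_scenario
from fourcmap.restriction import DPNII, digest_sequence


@pytest.fixture(scope="session")
def toy_genome():
    """Small deterministic genome with a handful of DpnII sites."""
    rng = np.random.default_rng(42)
    from fourcmap.synth import random_chromosome

    return {"chrA": random_chromosome(20_000, 1 / 250, rng)}


@pytest.fixture(scope="session")
def toy_map(toy_genome):
    return digest_sequence(toy_genome, DPNII)


@pytest.fixture(scope="session")
def scenario_result():
    """The standard synthetic scenario, run end to end once per session."""
    scenario = build_scenario(1)
    return run_scenario(scenario)
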