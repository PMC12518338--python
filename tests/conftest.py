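"""Shared fixtures: reference feedstocks and cached simulation results.

The full eleven-ratio sweep and the mono-digestion steady states are
session-scoped because each involves stiff ADM1 integration; tests share
them read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from codigest import feedstock as fsmod
from codigest import scenarios as sc
from codigest.adm1 import ADM1Parameters, simulate_cstr


@pytest.fixture(scope="session")
def reference_feedstocks():
    return fsmod.load_reference_feedstocks()


@pytest.fixture(scope="session")
def manure(reference_feedstocks):
    return reference_feedstocks["cattle_manure"]


@pytest.fixture(scope="session")
def prairie(reference_feedstocks):
    return reference_feedstocks["prairie_biomass"]


@pytest.fixture(scope="session")
def config():
    return sc.ScenarioConfig()


@pytest.fixture(scope="session")
def sweep_results(config):
    """All eleven blend ratios, all-biomass first."""
    results, table = sc.sweep(config)
    return results, table


@pytest.fixture(scope="session")
def manure_simulation(prairie, manure, config):
    """Steady-state ADM1 run of manure mono-digestion at packaged defaults."""
    influent = fsmod.blend_influent(prairie, manure, 0.0)
    return simulate_cstr(influent, ADM1Parameters(), HRT=config.HRT)


@pytest.fixture(scope="session")
def random_compositions():
    """10^4 randomized valid feedstock compositions (fixed seed)."""
    return sc.fixture_generator(seed=1234, n=10_000)
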