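from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from seatrace import SeafoodSustainabilityModel, WorldConfig, generate_world

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: baseline small world shared across tests (re-export hubs active,
#: all distortions on, matching the generator's default character)
BASE_CFG = WorldConfig(
    seed=1, n_countries=12, n_groups=3, n_hubs=2, trade_density=0.5,
)

#: clean world satisfying every estimator assumption: no re-exports, no
#: masked scores, no source disagreement, no labelling noise
CLEAN_KW = dict(
    reexport_fraction=0.0, missing_fmi_fraction=0.0,
    source_disagreement=None, farmed_fraction=0.0, nonfood_fraction=0.0,
)


def make_world(**kw):
    return generate_world(dataclasses.replace(BASE_CFG, **kw))


@pytest.fixture(scope="session")
def world1():
    """Seed-1 default-character small world."""
    return make_world()


@pytest.fixture(scope="session")
def world1_results(world1):
    return SeafoodSustainabilityModel.from_world(world1).fit()


@pytest.fixture(scope="session")
def clean_world():
    """Zero-re-export world in which the proportional estimator is exact."""
    return make_world(seed=7, n_countries=8, n_groups=2, n_hubs=1,
                      trade_density=0.6, **CLEAN_KW)
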