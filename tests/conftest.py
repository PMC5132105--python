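"""Shared fixtures: toy consortium members, media, database, tiny LP models."""

import itertools

import numpy as np
import pytest

import commfba as cf
from commfba.model import (
    Compartment,
    GeneAssociation,
    MetabolicModel,
    Metabolite,
    Reaction,
)


@pytest.fixture(scope="session")
def phototroph():
    return cf.make_toy_phototroph()


@pytest.fixture(scope="session")
def heterotroph():
    return cf.make_toy_heterotroph()


@pytest.fixture(scope="session")
def database():
    return cf.make_toy_database()


@pytest.fixture(scope="session")
def autotrophic():
    return cf.make_autotrophic_media()


@pytest.fixture(scope="session")
def glucose_minimal():
    return cf.make_glucose_minimal_media()


@pytest.fixture(scope="session")
def rich():
    return cf.make_rich_media()


@pytest.fixture(scope="session")
def community(phototroph, heterotroph):
    comm, _ = cf.build_compartmentalized([phototroph, heterotroph])
    return comm


from commfba.benchmarks import (  # noqa: E402  (re-exported for tests)
    enumerate_vertices,
    tiny_chain_model,
    vertex_fba_oracle,
    vertex_pfba_oracle,
)


@pytest.fixture
def chain_model():
    return tiny_chain_model()


@pytest.fixture
def chain_with_cycle():
    return tiny_chain_model(with_cycle=True)
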