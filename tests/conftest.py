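"""Shared fixtures: tiny hand-checkable networks and a small synthetic world."""

import numpy as np
import pytest

from netpharm.catalog_io import DTICatalog, DTIRecord
from netpharm.netinfer import build_network
from netpharm.substructures import SubstructureMatrix
from netpharm.synthgen import SynthConfig, gen_world, load_indication_fixture


@pytest.fixture
def toy_t1():
    """Drugs d1, d2; substructure s1 linked to both; target T1 linked to d2.

    Querying d1 (a new chemical) with gamma=0, beta=0.1, k=1 puts 0.45 on
    T1 and 0.55 on s1 by hand propagation.
    """
    catalog = DTICatalog((DTIRecord("d2", "T1"),))
    matrix = SubstructureMatrix(("d1", "d2"), ("s1",), np.array([[1], [1]]))
    return catalog, matrix, build_network(catalog, matrix)


@pytest.fixture(scope="session")
def small_world():
    """Default synthetic world, seed 42 (drug clusters sharing targets)."""
    return gen_world(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def indication_table():
    """Published 18-row indication screen (raw P, printed adjusted values)."""
    return load_indication_fixture()
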