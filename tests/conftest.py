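import numpy as np
import pytest

from spatialgem.model_io import MetabolicModel, parse_gpr
from spatialgem.synthetic_data import FIXTURE_NAMES, fixture_network


@pytest.fixture(params=FIXTURE_NAMES)
def fixture_pair(request):
    """(name, model, region expression vectors) for every fixture network."""
    model, expr = fixture_network(request.param)
    return request.param, model, expr


@pytest.fixture
def chain_model():
    return fixture_network("linear_chain")[0]


@pytest.fixture
def parallel_model():
    """Two parallel routes (ub 3 and 4) feeding biomass: optimum 7."""
    S = np.array(
        [
            # UP_A  UP_B  R_A  R_B  BIOMASS
            [1.0, 0.0, -1.0, 0.0, 0.0],  # A
            [0.0, 1.0, 0.0, -1.0, 0.0],  # B
            [0.0, 0.0, 1.0, 1.0, -1.0],  # P
        ]
    )
    return MetabolicModel(
        metabolite_ids=["A", "B", "P"],
        reaction_ids=["UP_A", "UP_B", "R_A", "R_B", "BIOMASS"],
        S=S,
        lb=np.zeros(5),
        ub=np.array([10.0, 10.0, 3.0, 4.0, 1000.0]),
        gpr=[None, None, parse_gpr("gA"), parse_gpr("gB"), None],
        subsystem=["Exchange", "Exchange", "Path", "Path", "Biomass"],
        gene_ids=["gA", "gB"],
        objective_id="BIOMASS",
    )


@pytest.fixture
def grid_coords():
    """200-spot rectangular grid at 200 μm pitch."""
    xs, ys = np.meshgrid(np.arange(10), np.arange(20), indexing="ij")
    return np.column_stack([xs.ravel(), ys.ravel()]) * 200.0
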