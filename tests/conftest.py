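import numpy as np
import pytest

from bivtwin.anatomy import solve_laplace
from bivtwin.mesh import make_biv_mesh, make_slab_mesh
from bivtwin.propagation import TwoCurrentModel, prepace_cell


@pytest.fixture(scope="session")
def slab():
    """1 x 1 x 0.5 cm slab at the 1000 um desk-scale default."""
    return make_slab_mesh((1.0, 1.0, 0.5), 1000.0)


@pytest.fixture(scope="session")
def slab_coords(slab):
    """Transmural (z) and apicobasal (x) Laplace coordinates on the slab."""
    tm = solve_laplace(slab, {"endo": 0.0, "epi": 1.0})
    ab = solve_laplace(slab, {"apex": 0.0, "base": 1.0})
    return tm, ab


@pytest.fixture(scope="session")
def biv():
    """Coarse idealized biventricular mesh."""
    return make_biv_mesh(target_edge_um=2500.0)


@pytest.fixture(scope="session")
def healthy_cell_state():
    """Prepaced resting state of the default cell at a 650 ms cycle."""
    model = TwoCurrentModel()
    state, apd, _ = prepace_cell(model, 650.0, min_beats=4)
    return model, state, float(apd)
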