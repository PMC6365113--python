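import numpy as np
import pandas as pd
import pytest

from hotroutes.hotspots import OccurrenceGrid
from hotroutes.trees import IndexedTree


@pytest.fixture
def two_tip():
    return IndexedTree.from_newick("(A:1.0,B:1.0);")


@pytest.fixture
def balanced4():
    return IndexedTree.from_newick("((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);")


@pytest.fixture
def caterpillar4():
    return IndexedTree.from_newick("(((A:1.0,B:1.0):1.0,C:2.0):1.0,D:3.0);")


def make_grid(occ_rows, nx=4, ny=3, cell_km=100.0, realms=None):
    """Tiny occurrence grid: occ_rows = [(species, x, y), ...]."""
    cells = []
    for x in range(nx):
        for y in range(ny):
            realm = "all" if realms is None else realms(x, y)
            cells.append((f"c{x}_{y}", x, y, realm))
    cells = pd.DataFrame(cells, columns=["cell_id", "x", "y", "realm"])
    occ = pd.DataFrame(
        [(sp, f"c{x}_{y}") for sp, x, y in occ_rows], columns=["species", "cell_id"]
    )
    return OccurrenceGrid(occ, cells, cell_km)


@pytest.fixture
def tiny_grid():
    # sp1 endemic to one cell; sp2 in two cells; sp3 widespread (4 cells)
    return make_grid([
        ("sp1", 0, 0),
        ("sp2", 0, 0), ("sp2", 1, 0),
        ("sp3", 0, 0), ("sp3", 1, 0), ("sp3", 2, 0), ("sp3", 3, 0),
    ])
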