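import numpy as np
import pandas as pd
import pytest

from voxatlas import synthetic as syn
from voxatlas.ontology import RegionHierarchy, RegionNode


@pytest.fixture(scope="session")
def truth_brain():
    return syn.make_brain(seed=7)


@pytest.fixture(scope="session")
def cells_and_slices(truth_brain):
    return syn.make_cells(truth_brain, n_slices=6, seed=7)


@pytest.fixture(scope="session")
def patchseq_small(truth_brain):
    return syn.make_patchseq(truth_brain, n_cells_per_ttype=40, seed=7)


def build_hierarchy(edges):
    """edges: list of (id, acronym, name, parent)."""
    nodes = [RegionNode(i, a, n, p) for i, a, n, p in edges]
    by_id = {n.region_id: n for n in nodes}
    for n in nodes:
        if n.parent_id is not None and n.parent_id in by_id:
            by_id[n.parent_id].children.append(n.region_id)
    return RegionHierarchy.from_nodes(nodes)


@pytest.fixture
def chain_hierarchy():
    return build_hierarchy(
        [(1, "root", "root", None), (2, "mid", "middle", 1), (3, "leaf", "leafy", 2)]
    )


@pytest.fixture
def toy_atlas():
    """3-region, 2-type atlas with one N/A row and one zero entry."""
    from voxatlas.densities import DensityAtlas

    dens = pd.DataFrame(
        [[100.0, 50.0], [0.0, 20.0], [np.nan, np.nan]],
        index=[10, 11, 12],
        columns=["A", "B"],
    )
    counts = dens.copy()
    vols = pd.Series([1.0, 2.0, 0.5], index=[10, 11, 12])
    return DensityAtlas(densities=dens, counts=counts, region_volumes=vols)
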