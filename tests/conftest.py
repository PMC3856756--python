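import dendropy
import numpy as np
import pandas as pd
import pytest

from gridphylo.gridding import CommunityMatrix
from gridphylo.simulate import SimulationConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """An 80-species, 12 x 10 landscape exercising every pipeline stage."""
    cfg = SimulationConfig(n_species=80, n_lon=12, n_lat=10, n_counties=24, seed=42)
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def two_clade_tree():
    """Two deep 4-tip clades: within-clade distance 2, between-clade 24."""
    nwk = "(((a:1,b:1):1,(c:1,d:1):1):10,((e:1,f:1):1,(g:1,h:1):1):10);"
    return dendropy.Tree.get(data=nwk, schema="newick", rooting="force-rooted")


def truth_matrix(bundle) -> CommunityMatrix:
    """Community matrix straight from the generator's true occupancy sets
    (no county coarsening)."""
    cells = list(bundle.truth.richness)
    species = sorted(bundle.truth.true_cells)
    m = np.zeros((len(cells), len(species)), dtype=np.int8)
    cid = {c: i for i, c in enumerate(cells)}
    for j, s in enumerate(species):
        for c in bundle.truth.true_cells[s]:
            m[cid[c], j] = 1
    life = dict(zip(bundle.occurrences["species"], bundle.occurrences["life_form"]))
    return CommunityMatrix(pd.DataFrame(m, index=cells, columns=species), life)
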