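import numpy as np
import pandas as pd
import pytest

import divgrid as dg


@pytest.fixture
def worked_tree() -> dg.RootedTree:
    """The three-species worked tree: ((A:1,B:1):1,C:2); total length 5."""
    return dg.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def worked_presence() -> np.ndarray:
    """Two cells: cell 0 holds {A, B}, cell 1 holds {B, C}."""
    return np.array([[True, True, False],
                     [False, True, True]])


@pytest.fixture
def worked_dissimilarity() -> pd.DataFrame:
    """D(A,B)=0.2, D(A,C)=D(B,C)=0.6 — joins at heights 0.1 and 0.3."""
    return pd.DataFrame(
        [[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]],
        index=list("ABC"), columns=list("ABC"),
    )


def random_world(seed: int, n_species: int = 30, rows: int = 8,
                 cols: int = 8) -> tuple[dg.RootedTree, np.ndarray, list]:
    """A random ultrametric tree plus random presence matrix: the generic
    fixture for conservation/monotonicity property checks."""
    rng = np.random.default_rng(seed)
    from divgrid.synthetic import simulate_phylogeny

    phy = simulate_phylogeny(n_species, seed=seed)
    species = sorted(phy.leaf_labels)
    n_cells = rows * cols
    presence = rng.random((n_cells, n_species)) < rng.uniform(0.05, 0.3)
    # every species needs at least one occupied cell
    for j in range(n_species):
        if not presence[:, j].any():
            presence[rng.integers(n_cells), j] = True
    return phy, presence, species
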