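import numpy as np
import pytest

import crestflow as cf
from crestflow.tree import ForkPath


@pytest.fixture(scope="session")
def y_data():
    """Noisy Y-trajectory embedding with ground truth (600 cells)."""
    emb, truth = cf.simulate_trajectory(cf.y_topology(), 600, 0.05, seed=11)
    return emb, truth


@pytest.fixture(scope="session")
def fitted_tree(y_data):
    emb, _ = y_data
    return cf.fit_principal_tree(emb, n_nodes=30, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """Default synthetic counts with low-quality cells (300 clean + 9 bad)."""
    emb, truth, expr = cf.default_dataset(
        n_cells=300, n_background=200, n_low_quality_cells=9, seed=5
    )
    return emb, truth, expr


def truth_fork_path(truth) -> ForkPath:
    """ForkPath built from generator truth (bypasses tree inference)."""
    t = truth.pseudotime
    seg = truth.segment
    lab = np.where(
        seg == "NC", "pre-fork", np.where(seg == "glial", "branch-1", "branch-2")
    )
    return ForkPath(
        cell_indices=np.arange(len(t)),
        branch_labels=lab,
        pseudotime=t,
        fork_pseudotime=1.0,
        fork_node=None,
        source=0,
        targets=(1, 2),
        node_labels={},
    )
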