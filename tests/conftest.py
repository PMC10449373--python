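import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sodanet import OtuTable, generate_study

warnings.filterwarnings("ignore", message="no samples in season")


@pytest.fixture
def tiny_table():
    """2 samples x 2 OTUs count table."""
    return OtuTable(
        pd.DataFrame([[3, 0], [1, 2]], index=["S1", "S2"], columns=["otuA", "otuB"]),
        unit="counts",
    )


def standard_planted_edges():
    """Ten mixed-sign, mixed-delay couplings among the first 20 core OTUs."""
    signs = [1, -1, 1, -1, 1, -1, 1, -1, 1, -1]
    delays = [0, 0, 0, 0, 1, 1, 1, -1, -1, 0]
    return [
        (f"core{2 * k:03d}", f"core{2 * k + 1:03d}", signs[k], delays[k], 0.9)
        for k in range(10)
    ]


@pytest.fixture(scope="session")
def planted_study():
    """One-lake study with the standard planted edge set (seed 0)."""
    return generate_study(
        n_lakes=1,
        n_times=14,
        n_core=40,
        n_noncore_per_lake=0,
        depth=5000,
        seed=0,
        planted_edges=standard_planted_edges(),
        desiccation={},
    )


@pytest.fixture(scope="session")
def default_study():
    """Five-lake, fourteen-occasion study with default desiccation (seed 7)."""
    return generate_study(seed=7)


def toy_pipeline_config(outdir, n_perm=300, seed=5):
    """Small two-lake synthetic pipeline configuration."""
    from sodanet import PipelineConfig

    return PipelineConfig(
        outdir=str(outdir),
        seed=seed,
        synthetic={
            "n_lakes": 2,
            "n_times": 14,
            "n_core": 12,
            "n_noncore_per_lake": 4,
            "depth": 1200,
            "desiccation": {"L2": ({7}, 0.5)},
        },
        n_perm=n_perm,
        alpha=0.05,
    )


def random_signed_graph(rng, max_nodes=8):
    """Random signed weighted graph for WI oracle checks."""
    import networkx as nx

    k = rng.integers(2, max_nodes + 1)
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if rng.random() < 0.5:
                w = rng.uniform(0.1, 1.0) * rng.choice([-1, 1])
                g.add_edge(i, j, weight=w)
    return g
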