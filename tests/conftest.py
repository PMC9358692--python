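import numpy as np
import pandas as pd
import pytest

from netprop import (
    GeneSet,
    SynthConfig,
    build_network,
    column_normalize,
    synth_network,
)
from netprop.net_io import ExpressionStudy


@pytest.fixture(scope="session")
def small_synth():
    """A small planted network shared by read-only tests."""
    cfg = SynthConfig(rng_seed=7, n_nodes=200, module_size=20, n_seed_genes=5)
    edges, idmap, truth = synth_network(cfg)
    return cfg, edges, idmap, truth


@pytest.fixture(scope="session")
def small_network(small_synth):
    _, edges, _, _ = small_synth
    net = build_network(edges, min_score=899)
    return net, column_normalize(net)


def make_study(values, n_case, cohort_id="test", genes=None):
    """Build an ExpressionStudy from a genes x samples array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    labels = pd.Series(
        ["case"] * n_case + ["control"] * (values.shape[1] - n_case),
        index=samples,
    )
    return ExpressionStudy(
        cohort_id=cohort_id,
        matrix=pd.DataFrame(values, index=genes, columns=samples),
        labels=labels,
    )


@pytest.fixture
def path_graph_network():
    """A--B--C path as an explicit EdgeTable -> Network."""
    edges = pd.DataFrame(
        [("A", "B", 950), ("B", "C", 950)],
        columns=["protein_a", "protein_b", "combined_score"],
    )
    net = build_network(edges, min_score=899)
    return net, column_normalize(net)
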