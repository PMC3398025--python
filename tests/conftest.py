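import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hubnet.graph_io import ExpressionMatrix


@pytest.fixture
def two_group_matrix():
    """4 genes x 6 samples, 3 case + 3 control, no missing values."""
    rng = np.random.default_rng(0)
    samples = ["c1", "c2", "c3", "n1", "n2", "n3"]
    df = pd.DataFrame(
        rng.normal(0, 1, size=(4, 6)),
        index=["g1", "g2", "g3", "g4"],
        columns=samples,
    )
    group = pd.Series(
        ["case", "case", "case", "control", "control", "control"], index=samples
    )
    return ExpressionMatrix(df, group)


@pytest.fixture
def triangle_plus_edge():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C"), ("D", "E")])
    return g


@pytest.fixture
def path_graph():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


def make_two_group(values, n_case, n_control, gene_ids=None):
    """Build an ExpressionMatrix from a 2-D array: first n_case cols are cases."""
    values = np.asarray(values, dtype=float)
    n_genes = values.shape[0]
    genes = gene_ids or [f"g{i}" for i in range(n_genes)]
    samples = [f"c{i}" for i in range(n_case)] + [f"n{i}" for i in range(n_control)]
    df = pd.DataFrame(values, index=genes, columns=samples)
    group = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    return ExpressionMatrix(df, group)
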