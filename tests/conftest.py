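import networkx as nx
import numpy as np
import pandas as pd
import pytest

from modwalk.expression import ExpressionProfile


def make_profile(activities: dict, p: float = 0.001) -> ExpressionProfile:
    """Profile with prescribed activities (fc = activity, all significant)."""
    genes = sorted(activities)
    table = pd.DataFrame(
        {
            "fc": [activities[g] for g in genes],
            "p": p,
            "p_adj": p,
            "activity": [abs(activities[g]) for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return ExpressionProfile(table)


def random_connected_graph(
    rng: np.random.Generator,
    n_max: int = 30,
    p: float = 0.35,
    weighted: bool = True,
) -> nx.Graph:
    """Random connected graph with uniform positive weights (for oracles)."""
    n = int(rng.integers(4, n_max + 1))
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            break
    for u, v in g.edges():
        g.edges[u, v]["weight"] = float(rng.uniform(0.1, 3.0)) if weighted else 1.0
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
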