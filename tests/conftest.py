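import numpy as np
import pandas as pd
import pytest

from omuecol.omu_table import AnnotationMap, OmuTable
from omuecol.simulate import (
    SyntheticSpec,
    sample_source_profile,
    simulate_neutral_assemblage,
)


@pytest.fixture
def small_table() -> OmuTable:
    """3 OMUs x 2 samples with easy hand arithmetic."""
    df = pd.DataFrame(
        [[0.0, 5.0], [1.0, 0.0], [4.0, 4.0]],
        index=["a", "b", "c"],
        columns=["s1", "s2"],
    )
    return OmuTable(df, level="MG", mode="type2")


@pytest.fixture
def annotation() -> AnnotationMap:
    return AnnotationMap(
        {
            "a": {"F1"},
            "b": {"F1", "F7"},
            "c": {"F2"},
        }
    )


@pytest.fixture(scope="session")
def neutral_table() -> OmuTable:
    """Medium neutral metacommunity reused by several test modules."""
    spec = SyntheticSpec(
        n_omu=200, n_samples=50, I_T=10_000, m=0.3, depth=10_000, seed=11
    )
    profile = sample_source_profile(spec)
    table, _ = simulate_neutral_assemblage(
        profile, spec.m, spec.I_T, spec.n_samples, spec.depth, seed=12
    )
    return table


def random_signed_graph(rng: np.random.Generator, n: int, p_edge: float = 0.45):
    """Random signed graph fixture shared by motif/salience oracles."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(f"n{i}" for i in range(n))
    nodes = sorted(G.nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                rho = rng.uniform(-1, 1)
                while abs(rho) < 0.05:
                    rho = rng.uniform(-1, 1)
                G.add_edge(
                    nodes[i], nodes[j],
                    rho=rho, sign="+" if rho > 0 else "-",
                    weight=1.0 / abs(rho),
                )
    return G
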