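"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately simple, brute-force implementations kept
separate from the library code paths they check: a dense linear solve for
the walk's fixed point, and explicit enumeration for the hypergeometric
tail.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netprio import (
    BenchmarkSpec,
    GeneRecord,
    SeedSet,
    WeightedNetwork,
    generate_benchmark,
)

DATA_DIR = Path(__file__).parent / "data"


# -- oracles ---------------------------------------------------------------


def dense_rwr_solve(network: WeightedNetwork, seed_genes, r: float) -> pd.Series:
    """Fixed point of p = (1-r) W p + r p0 by a dense linear solve."""
    nodes = network.nodes
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for a, b, w in network.edges():
        A[idx[a], idx[b]] = w
        A[idx[b], idx[a]] = w
    W = A / A.sum(axis=0, keepdims=True)
    p0 = np.zeros(n)
    for g in seed_genes:
        p0[idx[g]] = 1.0 / len(seed_genes)
    p = np.linalg.solve(np.eye(n) - (1.0 - r) * W, r * p0)
    return pd.Series(p, index=list(nodes))


def random_connected_network(
    n_nodes: int, edge_prob: float, rng: np.random.Generator
) -> WeightedNetwork:
    """Random connected weighted graph with STRING-range integer scores."""
    g = nx.gnp_random_graph(n_nodes, edge_prob, seed=int(rng.integers(2**31)))
    giant = max(nx.connected_components(g), key=len)
    edges = [
        (f"n{a:04d}", f"n{b:04d}", int(rng.integers(150, 1000)))
        for a, b in g.subgraph(giant).edges()
    ]
    return WeightedNetwork(edges)


# -- fixtures --------------------------------------------------------------


@pytest.fixture(scope="session")
def default_benchmark():
    """One default planted-module benchmark shared across the session."""
    return generate_benchmark(BenchmarkSpec())


@pytest.fixture
def toy_network() -> WeightedNetwork:
    """Five nodes: a hub 'c' plus a pendant chain, assorted scores."""
    return WeightedNetwork(
        [
            ("c", "l1", 600),
            ("c", "l2", 300),
            ("c", "a", 900),
            ("a", "b", 700),
        ]
    )


@pytest.fixture(scope="session")
def published_core_table() -> list[GeneRecord]:
    """The 33 reported core candidate epilepsy genes with their scores.

    Permutation FDR cells printed as "<0.001" correspond to zero exceedances
    out of 1000 permutations.
    """
    table = pd.read_csv(DATA_DIR / "core_candidate_table.tsv", sep="\t")
    records = []
    for row in table.itertuples(index=False):
        fdr_raw = str(row[3])
        below_resolution = fdr_raw.startswith("<")
        records.append(
            GeneRecord(
                symbol=row[0],
                identifier=row[1],
                probability=float(row[2]),
                fdr=0.0 if below_resolution else float(fdr_raw),
                mis=int(row[4]),
                mfs=float(row[5]),
                theta=0 if below_resolution else None,
                n_permutations=1000,
            )
        )
    return records
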