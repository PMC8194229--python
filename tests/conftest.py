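"""Shared fixtures: tiny expression matrices and hand-checkable graphs."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from genecomm.data import ExpressionMatrix


def make_expression(vals: np.ndarray, n_tumor: int, gene_prefix: str = "G") -> ExpressionMatrix:
    n_genes, n_samples = vals.shape
    genes = [f"{gene_prefix}{i:03d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    labels = pd.Series(
        ["tumor"] * n_tumor + ["normal"] * (n_samples - n_tumor), index=samples
    )
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples), labels)


@pytest.fixture
def two_block_matrix() -> ExpressionMatrix:
    """Noise-free two-block matrix: genes 0-9 elevated in samples 0-9,
    genes 10-19 elevated in samples 10-19."""
    vals = np.zeros((20, 20))
    vals[:10, :10] = 5.0
    vals[10:, 10:] = 5.0
    return make_expression(vals, n_tumor=10)


def unit_clique(nodes, weight: float = 1.0) -> nx.Graph:
    g = nx.Graph()
    nodes = list(nodes)
    g.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            g.add_edge(a, b, weight=weight)
    return g


def random_weighted_graph(rng: np.random.Generator, n_nodes: int, p_edge: float = 0.5) -> nx.Graph:
    g = nx.Graph()
    nodes = [f"n{i}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if rng.random() < p_edge:
                g.add_edge(a, b, weight=float(rng.uniform(0.05, 1.0)))
    return g


@pytest.fixture
def triangle_graph() -> nx.Graph:
    return unit_clique(["A", "B", "C"])
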