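"""Shared fixtures: small hand-built datasets and graph helpers."""
from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from diffconet import ExpressionDataset
from diffconet.coexpr_network import CoexpressionNetwork
from diffconet.harmonize import DISEASE, NORMAL


def make_dataset(
    values: np.ndarray,
    genes: list[str] | None = None,
    conditions: list[str] | None = None,
    batches: list[str] | None = None,
    tissue: str = "ACC",
) -> ExpressionDataset:
    """Build an ExpressionDataset from a raw matrix and per-sample labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(1, n_genes + 1)]
    conditions = conditions or [NORMAL] * (n_samples // 2) + [DISEASE] * (
        n_samples - n_samples // 2
    )
    batches = batches or ["b1"] * n_samples
    sample_ids = [f"s{i}" for i in range(1, n_samples + 1)]
    samples = pd.DataFrame(
        {"condition": conditions, "tissue": tissue, "batch": batches}, index=sample_ids
    )
    return ExpressionDataset(
        values=pd.DataFrame(values, index=genes, columns=sample_ids), samples=samples
    )


def net_from_edges(
    edges: list[tuple[str, str]], universe: list[str] | None = None, **labels
) -> CoexpressionNetwork:
    """CoexpressionNetwork from an explicit edge list (unit weights)."""
    graph = nx.Graph()
    graph.add_edges_from(edges)
    if universe is None:
        universe = sorted(graph.nodes)
    return CoexpressionNetwork(graph=graph, universe=tuple(universe), **labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
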