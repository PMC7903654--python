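"""Thresholded Pearson co-expression networks and their topology.

For one (tissue, condition) slice, every pair of genes in a chosen universe
is scored by the sample Pearson correlation across that condition's samples;
pairs with |r| at or above the threshold (default 0.5) become edges. Isolated
genes are excluded from the node set but counted against the universe as
unconnected nodes. The topology summary reports node/edge counts, the mean
local clustering coefficient (zero for degree < 2), graph density, and
Freeman degree centralization, plus degree histograms with a Gaussian kernel
density estimate for distribution-shape comparisons between conditions.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import ExpressionDataset

logger = logging.getLogger("diffconet")


class NetworkError(ValueError):
    """Raised for invalid network-construction inputs."""


@dataclass
class CoexpressionNetwork:
    """Undirected weighted graph over genes for one tissue and condition."""

    graph: nx.Graph
    universe: tuple[str, ...]
    tissue: str = ""
    condition: str = ""
    r_threshold: float = 0.5
    mode: str = "abs"

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_of(self, gene: str) -> int:
        return self.graph.degree(gene) if gene in self.graph else 0

    def degrees(self) -> np.ndarray:
        return np.array([d for _, d in self.graph.degree()], dtype=int)


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    n_unconnected: int
    clustering_coefficient: float
    density: float
    centralization: float

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_unconnected": self.n_unconnected,
            "clustering_coefficient": self.clustering_coefficient,
            "density": self.density,
            "centralization": self.centralization,
        }


def correlation_matrix(
    ds: ExpressionDataset,
    gene_subset: Sequence[str] | None = None,
    condition: str | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise Pearson r over one condition's samples.

    Constant genes have undefined correlation; their rows/columns are NaN
    and they are excluded from edge formation (count logged).
    """
    values = ds.values if condition is None else ds.condition_values(condition)
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in values.index]
        if missing:
            raise NetworkError(f"genes not in dataset: {missing[:5]}")
        values = values.loc[list(gene_subset)]
    x = values.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise NetworkError("need at least 3 samples to correlate")
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    n_const = int((~ok).sum())
    if n_const:
        logger.info("correlation_matrix: %d constant genes excluded", n_const)
    safe = np.where(ok, norms, 1.0)
    r = (centered @ centered.T) / np.outer(safe, safe)
    r = np.clip(r, -1.0, 1.0)
    r[~ok, :] = np.nan
    r[:, ~ok] = np.nan
    np.fill_diagonal(r, np.where(ok, 1.0, np.nan))
    return pd.DataFrame(r, index=values.index, columns=values.index)


def build_network(
    ds: ExpressionDataset,
    gene_subset: Sequence[str] | None = None,
    condition: str | None = None,
    r_threshold: float = 0.5,
    mode: str = "abs",
    tissue: str = "",
) -> CoexpressionNetwork:
    """Threshold the correlation matrix into a co-expression network.

    ``mode="abs"`` admits edges with |r| >= threshold; ``mode="positive"``
    requires r >= threshold. Self-interactions are never edges; genes without
    a qualifying partner are unconnected (absent from the node set).
    """
    if mode not in ("abs", "positive"):
        raise NetworkError(f"unknown threshold mode {mode!r}")
    corr = correlation_matrix(ds, gene_subset, condition)
    genes = list(corr.index)
    r = corr.to_numpy()
    score = np.abs(r) if mode == "abs" else r
    with np.errstate(invalid="ignore"):
        mask = score >= r_threshold
    np.fill_diagonal(mask, False)
    mask &= np.isfinite(r)
    graph = nx.Graph()
    iu, ju = np.nonzero(np.triu(mask, k=1))
    graph.add_weighted_edges_from(
        (genes[i], genes[j], float(r[i, j])) for i, j in zip(iu, ju)
    )
    return CoexpressionNetwork(
        graph=graph,
        universe=tuple(genes),
        tissue=tissue,
        condition=condition or "",
        r_threshold=r_threshold,
        mode=mode,
    )


def topology_summary(net: CoexpressionNetwork) -> TopologySummary:
    """Node/edge counts, mean local clustering, density, centralization.

    Local clustering is 0 for nodes of degree < 2; density is
    2E / (n (n-1)); centralization is Freeman's
    sum(k_max - k_i) / ((n-1)(n-2)), defined as 0 for n < 3. An empty
    network yields an all-zero summary with every universe gene unconnected.
    """
    n = net.n_nodes
    e = net.n_edges
    unconnected = len(net.universe) - n
    if n == 0:
        return TopologySummary(0, 0, unconnected, 0.0, 0.0, 0.0)
    clustering = float(nx.average_clustering(net.graph)) if n > 0 else 0.0
    density = 2.0 * e / (n * (n - 1)) if n >= 2 else 0.0
    degrees = net.degrees()
    if n >= 3:
        centralization = float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))
    else:
        centralization = 0.0
    return TopologySummary(n, e, unconnected, clustering, density, centralization)


@dataclass
class DegreeDensity:
    """Degree histogram, variance and Gaussian-kernel density estimate."""

    degrees: np.ndarray
    histogram: np.ndarray
    degree_variance: float
    grid: np.ndarray | None
    density: np.ndarray | None


def degree_density_curve(net: CoexpressionNetwork, grid_size: int = 512) -> DegreeDensity:
    """Degree distribution of the connected nodes.

    Variance uses the (n-1) denominator (0.0 for fewer than two nodes). The
    KDE uses a Gaussian kernel with Silverman's bandwidth on a grid of
    `grid_size` points spanning [0, max degree + 3 bandwidths]; it is omitted
    (None) when all degrees are equal.
    """
    degrees = np.sort(net.degrees())
    if degrees.size == 0:
        raise NetworkError("empty network has no degree distribution")
    histogram = np.bincount(degrees)
    variance = float(degrees.var(ddof=1)) if degrees.size >= 2 else 0.0
    grid = density = None
    if variance > 0:
        kde = stats.gaussian_kde(degrees.astype(float), bw_method="silverman")
        bandwidth = float(kde.factor * degrees.std(ddof=1))
        grid = np.linspace(0.0, degrees.max() + 3.0 * bandwidth, grid_size)
        density = kde(grid)
    return DegreeDensity(degrees, histogram, variance, grid, density)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def _sorted_edges(net: CoexpressionNetwork) -> list[tuple[str, str, float]]:
    edges = []
    for a, b, data in net.graph.edges(data=True):
        a, b = (a, b) if a <= b else (b, a)
        edges.append((a, b, float(data.get("weight", np.nan))))
    return sorted(edges)


def write_sif(net: CoexpressionNetwork, path) -> None:
    """SIF export: geneA <TAB> coexp <TAB> geneB."""
    with open(path, "w") as fh:
        for a, b, _ in _sorted_edges(net):
            fh.write(f"{a}\tcoexp\t{b}\n")


def write_network(net: CoexpressionNetwork, edges_path, meta_path) -> None:
    """Weighted edge TSV plus a JSON sidecar (universe, labels, threshold)."""
    pd.DataFrame(_sorted_edges(net), columns=["gene_a", "gene_b", "r"]).to_csv(
        edges_path, sep="\t", index=False
    )
    with open(meta_path, "w") as fh:
        json.dump(
            {
                "universe": list(net.universe),
                "tissue": net.tissue,
                "condition": net.condition,
                "r_threshold": net.r_threshold,
                "mode": net.mode,
            },
            fh,
            indent=2,
        )


def read_network(edges_path, meta_path) -> CoexpressionNetwork:
    edges = pd.read_csv(edges_path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    with open(meta_path) as fh:
        meta = json.load(fh)
    graph = nx.Graph()
    graph.add_weighted_edges_from(
        (row.gene_a, row.gene_b, float(row.r)) for row in edges.itertuples()
    )
    return CoexpressionNetwork(
        graph=graph,
        universe=tuple(meta["universe"]),
        tissue=meta["tissue"],
        condition=meta["condition"],
        r_threshold=float(meta["r_threshold"]),
        mode=meta["mode"],
    )


def topology_table(summaries: dict[str, TopologySummary]) -> pd.DataFrame:
    """Table-shaped view: one column per tissue x condition."""
    rows = [
        "Nodes",
        "Edges",
        "Unconnected nodes",
        "Clustering coefficient",
        "Density",
        "Centralization",
    ]
    data = {
        label: [
            s.n_nodes,
            s.n_edges,
            s.n_unconnected,
            s.clustering_coefficient,
            s.density,
            s.centralization,
        ]
        for label, s in summaries.items()
    }
    return pd.DataFrame(data, index=rows)
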