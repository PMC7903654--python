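"""Pathway enrichment and the pathway-gene crosstalk network.

Over-representation of a DEG list in curated gene sets is tested with the
one-sided Fisher exact (hypergeometric) test and Benjamini-Hochberg FDR
adjustment. Enriched pathways and their member DEGs are then assembled into
a bipartite pathway-gene network, optionally augmented with protein
interaction edges; node degrees are ranked and genes belonging to multiple
enriched pathways are reported as crosstalk genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("diffconet")


class EnrichmentError(ValueError):
    """Raised for invalid enrichment inputs."""


# ---------------------------------------------------------------------------
# GMT gene-set container
# ---------------------------------------------------------------------------


@dataclass
class GeneSets:
    """Ordered collection of named gene sets (GMT dialect)."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]


def read_gmt(path) -> GeneSets:
    """Read a GMT file: name <TAB> description <TAB> gene1 <TAB> gene2 ...

    A line with a single tab-separated field after the name is treated as a
    description with no genes; blank lines are skipped.
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            name = fields[0]
            descriptions[name] = fields[1] if len(fields) > 1 else ""
            sets[name] = tuple(g for g in fields[2:] if g)
    return GeneSets(sets=sets, descriptions=descriptions)


def write_gmt(gene_sets: GeneSets, path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.sets.items():
            desc = gene_sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Fisher / hypergeometric enrichment
# ---------------------------------------------------------------------------


def _select_degs(deg_genes, direction_mode: str) -> set[str]:
    """Accept a plain gene collection or a DEG table with direction info."""
    if direction_mode not in ("all", "up", "down"):
        raise EnrichmentError(f"unknown direction_mode {direction_mode!r}")
    if isinstance(deg_genes, pd.DataFrame):
        tbl = deg_genes[deg_genes["is_deg"]]
        if direction_mode != "all":
            tbl = tbl[tbl["direction"] == direction_mode]
        return set(tbl.index)
    if direction_mode != "all":
        raise EnrichmentError(
            "direction_mode other than 'all' requires a DEG table with directions"
        )
    return set(deg_genes)


def fisher_enrichment(
    deg_genes,
    universe: Iterable[str],
    gene_sets: GeneSets | Mapping[str, Sequence[str]],
    direction_mode: str = "all",
    p_threshold: float = 0.05,
    gate: str = "raw",
) -> pd.DataFrame:
    """One-sided over-representation test of `deg_genes` in each gene set.

    Pathways are intersected with `universe` before testing; zero-overlap
    pathways are skipped with a log line. ``gate`` selects whether the
    ``is_enriched`` flag compares the raw p (default, the study's rule) or
    the BH-adjusted p against `p_threshold`.

    Returns a DataFrame indexed by pathway with columns
    ``n_pathway, n_hits, p, p_adj, is_enriched, hit_genes``.
    """
    universe = set(universe)
    if not universe:
        raise EnrichmentError("empty universe")
    if gate not in ("raw", "fdr"):
        raise EnrichmentError(f"unknown gate {gate!r}")
    degs = _select_degs(deg_genes, direction_mode) & universe
    if not degs:
        raise EnrichmentError("empty DEG set")
    sets = gene_sets.sets if isinstance(gene_sets, GeneSets) else dict(gene_sets)

    rows = []
    for name, members in sets.items():
        in_universe = set(members) & universe
        if not in_universe:
            logger.info("fisher_enrichment: pathway %s has no universe overlap; skipped", name)
            continue
        hits = sorted(in_universe & degs)
        # P(X >= k) for X ~ Hypergeom(N=|universe|, K=|degs|, n=|pathway|)
        p = float(stats.hypergeom.sf(len(hits) - 1, len(universe), len(degs), len(in_universe)))
        rows.append((name, len(in_universe), len(hits), min(p, 1.0), hits))
    if not rows:
        raise EnrichmentError("no pathway overlaps the universe")
    df = pd.DataFrame(rows, columns=["pathway", "n_pathway", "n_hits", "p", "hit_genes"])
    df = df.set_index("pathway")
    df["p_adj"] = multipletests(df["p"].values, method="fdr_bh")[1]
    gated = df["p"] if gate == "raw" else df["p_adj"]
    df["is_enriched"] = gated < p_threshold
    df.attrs["direction_mode"] = direction_mode
    df.attrs["gate"] = gate
    return df[["n_pathway", "n_hits", "p", "p_adj", "is_enriched", "hit_genes"]]


def write_enrichment(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["hit_genes"] = out["hit_genes"].map(",".join)
    out.index.name = "pathway"
    out.to_csv(path, sep="\t")


def read_enrichment(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    df["hit_genes"] = df["hit_genes"].fillna("").map(
        lambda s: [g for g in str(s).split(",") if g]
    )
    df["is_enriched"] = df["is_enriched"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Pathway-gene bipartite network
# ---------------------------------------------------------------------------


@dataclass
class BipartiteNetwork:
    """Pathway-gene membership graph, optionally with gene-gene interactions.

    ``degree`` counts membership incidences per node; interaction edges are
    stored always but contribute to gene degree only when
    ``count_interactions_in_degree`` is set (off by default, so pathway
    degrees equal gene-hit counts).
    """

    pathway_nodes: tuple[str, ...]
    gene_nodes: tuple[str, ...]
    membership_edges: tuple[tuple[str, str], ...]
    interaction_edges: tuple[tuple[str, str], ...]
    degree: dict[str, int]
    count_interactions_in_degree: bool = False


def build_pathway_gene_network(
    enrichment: pd.DataFrame,
    deg_genes: Iterable[str],
    interactions: Iterable[tuple[str, str]] | None = None,
    count_interactions_in_degree: bool = False,
) -> BipartiteNetwork:
    """Assemble the pathway-gene complex network from enriched pathways.

    Gene nodes are the DEGs belonging to at least one enriched pathway; a
    membership edge joins each enriched pathway to each of its member DEGs.
    Interaction pairs with both endpoints among the gene nodes are retained
    as gene-gene edges.
    """
    enriched = enrichment[enrichment["is_enriched"]]
    if enriched.empty:
        raise EnrichmentError("no enriched pathway; cannot build the network")
    degs = set(deg_genes)
    membership = []
    for name, row in enriched.iterrows():
        for g in row["hit_genes"]:
            if g in degs:
                membership.append((name, g))
    membership = tuple(sorted(set(membership)))
    gene_nodes = tuple(sorted({g for _, g in membership}))
    pathway_nodes = tuple(enriched.index)

    inter: set[tuple[str, str]] = set()
    gene_set = set(gene_nodes)
    for a, b in interactions or ():
        if a == b:
            continue
        if a in gene_set and b in gene_set:
            inter.add((min(a, b), max(a, b)))
    interaction_edges = tuple(sorted(inter))

    degree: dict[str, int] = {n: 0 for n in pathway_nodes}
    degree.update({g: 0 for g in gene_nodes})
    for pw, g in membership:
        degree[pw] += 1
        degree[g] += 1
    if count_interactions_in_degree:
        for a, b in interaction_edges:
            degree[a] += 1
            degree[b] += 1
    return BipartiteNetwork(
        pathway_nodes=pathway_nodes,
        gene_nodes=gene_nodes,
        membership_edges=membership,
        interaction_edges=interaction_edges,
        degree=degree,
        count_interactions_in_degree=count_interactions_in_degree,
    )


def rank_top_degree(
    net: BipartiteNetwork, top_n: int = 10
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Top-N pathways and genes by degree (descending), ties by name."""
    if not net.pathway_nodes and not net.gene_nodes:
        raise EnrichmentError("empty network")

    def top(nodes):
        ranked = sorted(nodes, key=lambda n: (-net.degree[n], n))
        return [(n, net.degree[n]) for n in ranked[:top_n]]

    return top(net.pathway_nodes), top(net.gene_nodes)


def find_crosstalk_genes(
    net: BipartiteNetwork, min_pathways: int = 2
) -> dict[str, tuple[str, ...]]:
    """Genes with membership in at least `min_pathways` distinct pathways."""
    by_gene: dict[str, set[str]] = {}
    for pw, g in net.membership_edges:
        by_gene.setdefault(g, set()).add(pw)
    return {
        g: tuple(sorted(pws))
        for g, pws in sorted(by_gene.items())
        if len(pws) >= min_pathways
    }


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def write_bipartite_sif(net: BipartiteNetwork, path) -> None:
    """SIF export with edge types ``member`` and ``interacts``."""
    with open(path, "w") as fh:
        for pw, g in net.membership_edges:
            fh.write(f"{pw}\tmember\t{g}\n")
        for a, b in net.interaction_edges:
            fh.write(f"{a}\tinteracts\t{b}\n")


def read_bipartite_sif(path) -> tuple[tuple[tuple[str, str], ...], tuple[tuple[str, str], ...]]:
    """Read back a bipartite SIF into (membership_edges, interaction_edges)."""
    membership, inter = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            a, kind, b = line.rstrip("\n").split("\t")
            (membership if kind == "member" else inter).append((a, b))
    return tuple(membership), tuple(inter)


def write_rankings(
    top_pathways: list[tuple[str, int]], top_genes: list[tuple[str, int]], path
) -> None:
    """Table-shaped TSV: Pathway, Degree_path, Gene, Degree_gene rows."""
    n = max(len(top_pathways), len(top_genes))
    rows = []
    for i in range(n):
        pw, dpw = top_pathways[i] if i < len(top_pathways) else ("", "")
        g, dg = top_genes[i] if i < len(top_genes) else ("", "")
        rows.append((pw, dpw, g, dg))
    pd.DataFrame(rows, columns=["Pathway", "Degree_path", "Gene", "Degree_gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_interactions(path) -> list[tuple[str, str]]:
    """Two-column TSV (gene_a, gene_b), undirected, header row expected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [tuple(r) for r in df.iloc[:, :2].itertuples(index=False)]


def write_interactions(edges: Iterable[tuple[str, str]], path) -> None:
    pd.DataFrame(edges, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)
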