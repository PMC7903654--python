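"""Fisher enrichment oracle, bipartite network assembly, and crosstalk."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diffconet import (
    GeneSets,
    build_pathway_gene_network,
    find_crosstalk_genes,
    fisher_enrichment,
    rank_top_degree,
    read_gmt,
    write_gmt,
)
from diffconet.pathway_crosstalk import (
    EnrichmentError,
    read_bipartite_sif,
    read_enrichment,
    read_interactions,
    write_bipartite_sif,
    write_enrichment,
    write_interactions,
    write_rankings,
)


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) from the log-gamma form of the hypergeometric pmf."""

    def log_comb(a, b):
        if b < 0 or b > a:
            return -math.inf
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.exp(log_comb(K, x) + log_comb(N - K, n - x) - log_comb(N, n))
    return min(total, 1.0)


UNIVERSE = [f"u{i}" for i in range(10)]


class TestFisherEnrichment:
    def test_frozen_perfect_overlap(self):
        """5 DEGs of 10, pathway = the same 5 genes: p = 1/C(10,5) = 1/252."""
        degs = set(UNIVERSE[:5])
        sets = {"P": tuple(UNIVERSE[:5])}
        df = fisher_enrichment(degs, UNIVERSE, sets)
        assert df.loc["P", "p"] == pytest.approx(1.0 / 252.0, rel=1e-12)
        assert df.loc["P", "n_hits"] == 5
        assert df.loc["P", "is_enriched"]

    def test_matches_log_gamma_oracle_on_random_margins(self, rng):
        for _ in range(200):
            N = int(rng.integers(10, 120))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = [f"g{i}" for i in range(N)]
            degs = set(rng.choice(universe, size=K, replace=False))
            members = tuple(rng.choice(universe, size=n, replace=False))
            k = len(set(members) & degs)
            if k == 0:
                continue
            df = fisher_enrichment(degs, universe, {"P": members})
            assert df.loc["P", "p"] == pytest.approx(
                hypergeom_tail_oracle(k, N, K, n), rel=1e-10
            )

    def test_matches_scipy_fisher_exact(self, rng):
        for _ in range(30):
            N = int(rng.integers(15, 60))
            universe = [f"g{i}" for i in range(N)]
            degs = set(rng.choice(universe, size=int(rng.integers(2, N // 2)), replace=False))
            members = tuple(rng.choice(universe, size=int(rng.integers(2, N // 2)), replace=False))
            k = len(set(members) & degs)
            if k == 0:
                continue
            df = fisher_enrichment(degs, universe, {"P": members})
            n, K = len(members), len(degs)
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            _, p_ref = stats.fisher_exact(table, alternative="greater")
            assert df.loc["P", "p"] == pytest.approx(float(p_ref), rel=1e-9)

    def test_bh_and_fdr_gate(self):
        degs = set(UNIVERSE[:5])
        sets = {
            "hit": tuple(UNIVERSE[:5]),
            "half": tuple(UNIVERSE[3:8]),
            "miss_mostly": tuple(UNIVERSE[4:9]),
        }
        raw = fisher_enrichment(degs, UNIVERSE, sets, gate="raw")
        fdr = fisher_enrichment(degs, UNIVERSE, sets, gate="fdr")
        p = raw["p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1].clip(max=1.0)
        expected = np.empty(m)
        expected[order] = adj
        assert np.allclose(raw["p_adj"].to_numpy(), expected, atol=1e-12)
        assert (fdr["is_enriched"] == (fdr["p_adj"] < 0.05)).all()
        assert (raw["is_enriched"] == (raw["p"] < 0.05)).all()

    def test_zero_overlap_pathway_skipped(self):
        degs = set(UNIVERSE[:3])
        sets = {"inside": tuple(UNIVERSE[:3]), "outside": ("x1", "x2")}
        df = fisher_enrichment(degs, UNIVERSE, sets)
        assert list(df.index) == ["inside"]

    def test_direction_modes_with_deg_table(self):
        table = pd.DataFrame(
            {
                "is_deg": [True, True, True, False],
                "direction": ["up", "down", "up", "up"],
            },
            index=["u0", "u1", "u2", "u3"],
        )
        sets = {"P": tuple(UNIVERSE[:4])}
        up = fisher_enrichment(table, UNIVERSE, sets, direction_mode="up")
        down = fisher_enrichment(table, UNIVERSE, sets, direction_mode="down")
        allm = fisher_enrichment(table, UNIVERSE, sets, direction_mode="all")
        assert up.loc["P", "hit_genes"] == ["u0", "u2"]
        assert down.loc["P", "hit_genes"] == ["u1"]
        assert allm.loc["P", "n_hits"] == 3

    def test_invalid_inputs(self):
        with pytest.raises(EnrichmentError):
            fisher_enrichment({"u0"}, [], {"P": ("u0",)})
        with pytest.raises(EnrichmentError):
            fisher_enrichment(set(), UNIVERSE, {"P": ("u0",)})
        with pytest.raises(EnrichmentError):
            fisher_enrichment({"u0"}, UNIVERSE, {"P": ("u0",)}, direction_mode="sideways")
        with pytest.raises(EnrichmentError):
            fisher_enrichment({"u0"}, UNIVERSE, {"P": ("u0",)}, gate="bonferroni")


def _enrichment_fixture():
    """Two enriched pathways sharing gene u1; one non-enriched."""
    return pd.DataFrame(
        {
            "n_pathway": [3, 3, 3],
            "n_hits": [3, 2, 0],
            "p": [0.001, 0.01, 0.9],
            "p_adj": [0.003, 0.015, 0.9],
            "is_enriched": [True, True, False],
            "hit_genes": [["u0", "u1", "u2"], ["u1", "u3"], []],
        },
        index=["P1", "P2", "P3"],
    )


class TestBipartiteNetwork:
    def test_assembly_and_degrees(self):
        net = build_pathway_gene_network(_enrichment_fixture(), ["u0", "u1", "u2", "u3"])
        assert net.pathway_nodes == ("P1", "P2")
        assert net.gene_nodes == ("u0", "u1", "u2", "u3")
        assert net.degree["P1"] == 3 and net.degree["P2"] == 2
        assert net.degree["u1"] == 2 and net.degree["u0"] == 1

    def test_interactions_filtered_and_degree_flag(self):
        inter = [("u0", "u1"), ("u0", "zzz"), ("u1", "u0"), ("u2", "u2")]
        net = build_pathway_gene_network(
            _enrichment_fixture(), ["u0", "u1", "u2", "u3"], interactions=inter
        )
        assert net.interaction_edges == (("u0", "u1"),)
        assert net.degree["u0"] == 1  # membership only by default
        net2 = build_pathway_gene_network(
            _enrichment_fixture(),
            ["u0", "u1", "u2", "u3"],
            interactions=inter,
            count_interactions_in_degree=True,
        )
        assert net2.degree["u0"] == 2

    def test_non_deg_hits_excluded(self):
        net = build_pathway_gene_network(_enrichment_fixture(), ["u1"])
        assert net.gene_nodes == ("u1",)
        assert net.degree["P1"] == 1

    def test_no_enriched_pathway_errors(self):
        df = _enrichment_fixture()
        df["is_enriched"] = False
        with pytest.raises(EnrichmentError):
            build_pathway_gene_network(df, ["u0"])

    def test_rank_top_degree_tie_break(self):
        net = build_pathway_gene_network(_enrichment_fixture(), ["u0", "u1", "u2", "u3"])
        top_pw, top_genes = rank_top_degree(net, top_n=2)
        assert top_pw == [("P1", 3), ("P2", 2)]
        assert top_genes == [("u1", 2), ("u0", 1)]  # u0 beats u2/u3 by name

    def test_crosstalk_genes(self):
        net = build_pathway_gene_network(_enrichment_fixture(), ["u0", "u1", "u2", "u3"])
        assert find_crosstalk_genes(net) == {"u1": ("P1", "P2")}
        assert find_crosstalk_genes(net, min_pathways=1)["u0"] == ("P1",)


class TestIO:
    def test_gmt_round_trip(self, tmp_path):
        gs = GeneSets(
            sets={"A": ("g1", "g2"), "B": ("g3",)},
            descriptions={"A": "first", "B": ""},
        )
        write_gmt(gs, tmp_path / "x.gmt")
        back = read_gmt(tmp_path / "x.gmt")
        assert back.sets == gs.sets
        assert back.descriptions["A"] == "first"

    def test_enrichment_round_trip(self, tmp_path):
        df = _enrichment_fixture()
        write_enrichment(df, tmp_path / "e.tsv")
        back = read_enrichment(tmp_path / "e.tsv")
        assert list(back.index) == list(df.index)
        assert back["is_enriched"].tolist() == df["is_enriched"].tolist()
        assert back.loc["P1", "hit_genes"] == ["u0", "u1", "u2"]
        assert back.loc["P3", "hit_genes"] == []

    def test_bipartite_sif_round_trip(self, tmp_path):
        net = build_pathway_gene_network(
            _enrichment_fixture(), ["u0", "u1", "u2", "u3"], interactions=[("u1", "u0")]
        )
        write_bipartite_sif(net, tmp_path / "b.sif")
        membership, inter = read_bipartite_sif(tmp_path / "b.sif")
        assert membership == net.membership_edges
        assert inter == net.interaction_edges

    def test_rankings_format(self, tmp_path):
        write_rankings([("P1", 3)], [("g1", 2), ("g2", 1)], tmp_path / "r.tsv")
        df = pd.read_csv(tmp_path / "r.tsv", sep="\t")
        assert list(df.columns) == ["Pathway", "Degree_path", "Gene", "Degree_gene"]
        assert len(df) == 2
        assert df.loc[0, "Pathway"] == "P1" and df.loc[1, "Gene"] == "g2"

    def test_interactions_round_trip(self, tmp_path):
        edges = [("a", "b"), ("c", "d")]
        write_interactions(edges, tmp_path / "i.tsv")
        assert read_interactions(tmp_path / "i.tsv") == edges
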