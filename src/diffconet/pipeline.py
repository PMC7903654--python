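"""End-to-end orchestration of the differential co-expression analysis.

A single configuration drives the full chain: obtain expression data (from
files or the synthetic generator), harmonize batches, call DEGs per tissue,
build per-condition co-expression networks on the DEG universe, quantify
connectivity gain/loss and test it, enrich pathways, assemble the
pathway-gene crosstalk network, and evaluate the top-degree genes. Every
intermediate artifact is written to the output directory and the results are
consolidated in a machine-readable JSON report that is byte-identical across
runs with the same configuration and seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .harmonize import (
    DISEASE,
    NORMAL,
    ExpressionDataset,
    collapse_probes,
    merge_datasets,
    read_probe_map,
    zscore_standardize,
)
from .synthetic_data import (
    SynthConfig,
    generate_expression_pair,
    generate_interaction_edges,
    generate_pathway_gmt,
)
from .diffexpr import call_degs, deg_genes, deg_overlap, write_deg_table, write_overlap
from .coexpr_network import (
    build_network,
    degree_density_curve,
    topology_summary,
    topology_table,
    write_network,
    write_sif,
)
from .diffnet import (
    DiffNetError,
    connectivity_delta,
    connectivity_wilcoxon,
    cross_tissue_comparison,
    gain_loss_summary,
    write_deltas,
)
from .pathway_crosstalk import (
    EnrichmentError,
    GeneSets,
    build_pathway_gene_network,
    find_crosstalk_genes,
    fisher_enrichment,
    rank_top_degree,
    read_gmt,
    read_interactions,
    write_bipartite_sif,
    write_enrichment,
    write_gmt,
    write_interactions,
    write_rankings,
)
from .gene_eval import candidate_gene_table, write_evaluation

logger = logging.getLogger("diffconet")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Inputs, thresholds and flags for one pipeline run.

    Exactly one of ``synth`` or the ``expression``/``metadata`` file lists
    must be provided. File inputs may span several datasets per tissue; the
    tissue label of each sample comes from the metadata table.
    """

    outdir: str = "diffconet_out"
    synth: SynthConfig | None = None
    expression: list[str] = field(default_factory=list)
    metadata: list[str] = field(default_factory=list)
    probe_map: str | None = None
    gmt: str | None = None
    interactions: str | None = None
    # thresholds
    p_deg: float = 0.05
    effect_threshold: float = 0.0
    r_threshold: float = 0.5
    p_enrich: float = 0.05
    top_n: int = 10
    min_pathways: int = 2
    # flags
    corr_mode: str = "abs"  # abs | positive
    paired: bool = True
    hprd_degree: bool = False
    enrichment_gate: str = "raw"  # raw | fdr
    # synthetic fixture knobs (used only with synth input)
    gmt_n_pathways: int = 16
    gmt_overlap: float = 0.8
    interaction_density_within: float = 0.5
    interaction_density_background: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if (self.synth is None) == (not self.expression):
            pass
        if self.synth is not None and self.expression:
            raise PipelineConfigError("provide either a synth block or input paths, not both")
        if self.synth is None and not self.expression:
            raise PipelineConfigError("provide a synth block or input paths")
        if self.expression and len(self.expression) != len(self.metadata):
            raise PipelineConfigError("expression and metadata path lists must align")
        for name, lo, hi in (
            ("p_deg", 0.0, 1.0),
            ("p_enrich", 0.0, 1.0),
            ("r_threshold", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise PipelineConfigError(f"{name} must lie in [{lo}, {hi}]")
        if self.top_n < 1 or self.min_pathways < 1:
            raise PipelineConfigError("top_n and min_pathways must be >= 1")
        if self.corr_mode not in ("abs", "positive"):
            raise PipelineConfigError("corr_mode must be 'abs' or 'positive'")
        if self.enrichment_gate not in ("raw", "fdr"):
            raise PipelineConfigError("enrichment_gate must be 'raw' or 'fdr'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synth is not None:
            d["synth"] = dataclasses.asdict(self.synth)
            d["synth"]["tissues"] = list(self.synth.tissues)
            d["synth"]["alias_shared_genes"] = list(self.synth.alias_shared_genes)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        synth = doc.pop("synth", None)
        cfg = cls(**doc)
        if synth is not None:
            if "tissues" in synth:
                synth["tissues"] = tuple(synth["tissues"])
            if "alias_shared_genes" in synth:
                synth["alias_shared_genes"] = tuple(synth["alias_shared_genes"])
            cfg.synth = SynthConfig(**synth)
        return cfg

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # the output location is not part of the analysis
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _jsonable(obj: Any) -> Any:
    """Recursively convert to JSON-safe plain python (non-finite -> None)."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _load_inputs(config: PipelineConfig, outdir: Path):
    """Stage 1: simulate or read expression data, gene sets, interactions."""
    truth = None
    gene_sets = None
    interactions = None
    if config.synth is not None:
        synth = dataclasses.replace(config.synth, seed=config.seed)
        ds_a, ds_b, truth = generate_expression_pair(synth)
        datasets = {synth.tissues[0]: [ds_a], synth.tissues[1]: [ds_b]}
        collection = generate_pathway_gmt(
            truth,
            n_pathways=config.gmt_n_pathways,
            overlap_fraction=config.gmt_overlap,
            seed=config.seed,
        )
        gene_sets = collection.gene_sets
        interactions = generate_interaction_edges(
            truth,
            density_within=config.interaction_density_within,
            density_background=config.interaction_density_background,
            seed=config.seed,
        )
        truth.to_json(outdir / "truth.json")
        with open(outdir / "pathway_truth.json", "w") as fh:
            json.dump(
                {
                    "tissue": collection.tissue,
                    "enrichment_positive": sorted(collection.enrichment_positive),
                    "crosstalk_genes": {
                        g: list(p) for g, p in collection.crosstalk_genes.items()
                    },
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        write_gmt(gene_sets, outdir / "pathways.gmt")
        write_interactions(interactions, outdir / "interactions.tsv")
        for tissue, ds_list in datasets.items():
            ds_list[0].to_tsv(
                outdir / f"expression_{tissue}.tsv", outdir / f"metadata_{tissue}.tsv"
            )
    else:
        probe_map = read_probe_map(config.probe_map) if config.probe_map else None
        datasets = {}
        for expr_path, meta_path in zip(config.expression, config.metadata):
            ds = ExpressionDataset.from_tsv(expr_path, meta_path)
            if probe_map is not None:
                ds = collapse_probes(ds.values, probe_map, ds.samples)
            for tissue, meta in ds.samples.groupby("tissue", sort=False):
                sub = ExpressionDataset(values=ds.values[meta.index], samples=meta)
                datasets.setdefault(str(tissue), []).append(sub)
        if config.gmt:
            gene_sets = read_gmt(config.gmt)
        if config.interactions:
            interactions = read_interactions(config.interactions)
    return datasets, truth, gene_sets, interactions


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the consolidated report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    manifest: dict[str, str] = {}

    def stage(name: str, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            manifest[name] = "failed"
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
            logger.removeHandler(log_handler)
            log_handler.close()
            raise PipelineStageError(name, exc) from exc
        manifest[name] = "completed"
        return result

    try:
        datasets, truth, gene_sets, interactions = stage(
            "load", _load_inputs, config, outdir
        )
        tissues = list(datasets)
        report: dict[str, Any] = {
            "provenance": {
                "package": "diffconet",
                "version": __version__,
                "seed": config.seed,
                "config_sha256": config.config_hash(),
            },
            "tissues": tissues,
        }

        # -- harmonize ------------------------------------------------------
        def _harmonize():
            harmonized = {}
            for tissue, ds_list in datasets.items():
                std = [zscore_standardize(ds) for ds in ds_list]
                merged = std[0] if len(std) == 1 else merge_datasets(std, tissue=tissue)
                merged.to_tsv(
                    outdir / f"harmonized_{tissue}.tsv",
                    outdir / f"harmonized_metadata_{tissue}.tsv",
                )
                harmonized[tissue] = merged
            return harmonized

        harmonized = stage("harmonize", _harmonize)

        # -- differential expression ---------------------------------------
        def _deg():
            tables = {}
            for tissue, ds in harmonized.items():
                tbl = call_degs(ds, config.p_deg, config.effect_threshold)
                write_deg_table(tbl, outdir / f"deg_{tissue}.tsv")
                tables[tissue] = tbl
            return tables

        deg_tables = stage("diffexpr", _deg)
        deg_sets = {t: deg_genes(tbl) for t, tbl in deg_tables.items()}
        report["deg"] = {
            t: {
                "n_genes": int(len(tbl)),
                "n_deg": int(tbl["is_deg"].sum()),
                "n_up": int((tbl["is_deg"] & (tbl["direction"] == "up")).sum()),
                "n_down": int((tbl["is_deg"] & (tbl["direction"] == "down")).sum()),
            }
            for t, tbl in deg_tables.items()
        }
        if len(tissues) == 2:
            only_a, shared, only_b = deg_overlap(deg_sets[tissues[0]], deg_sets[tissues[1]])
            report["deg_overlap"] = {"only_a": only_a, "shared": shared, "only_b": only_b}
            write_overlap((only_a, shared, only_b), outdir / "deg_overlap.json")

        # -- co-expression networks ----------------------------------------
        def _networks():
            nets = {}
            for tissue, ds in harmonized.items():
                universe = sorted(deg_sets[tissue])
                for condition in (NORMAL, DISEASE):
                    net = build_network(
                        ds,
                        gene_subset=universe,
                        condition=condition,
                        r_threshold=config.r_threshold,
                        mode=config.corr_mode,
                        tissue=tissue,
                    )
                    label = f"{tissue}_{condition}"
                    write_sif(net, outdir / f"network_{label}.sif")
                    write_network(
                        net,
                        outdir / f"network_{label}.tsv",
                        outdir / f"network_{label}.json",
                    )
                    nets[(tissue, condition)] = net
            return nets

        networks = stage("network", _networks)
        summaries = {
            f"{t}_{c}": topology_summary(net) for (t, c), net in networks.items()
        }
        report["topology"] = {k: s.to_dict() for k, s in summaries.items()}
        tbl = topology_table(summaries)
        tbl.index.name = "summary"
        tbl.to_csv(outdir / "topology_table.tsv", sep="\t")
        report["degree_variance"] = {
            f"{t}_{c}": (
                degree_density_curve(net).degree_variance if net.n_nodes else None
            )
            for (t, c), net in networks.items()
        }

        # -- connectivity comparison ---------------------------------------
        def _diffnet():
            out = {}
            for tissue in tissues:
                normal = networks[(tissue, NORMAL)]
                disease = networks[(tissue, DISEASE)]
                if not normal.universe or not disease.universe:
                    out[tissue] = None
                    continue
                deltas = connectivity_delta(normal, disease)
                write_deltas(deltas, outdir / f"connectivity_{tissue}.tsv")
                summary = gain_loss_summary(deltas)
                try:
                    test = connectivity_wilcoxon(deltas, paired=config.paired)
                    test_doc = {
                        "W": test.statistic,
                        "n_effective": test.n_effective,
                        "p": test.p,
                        "method": test.method,
                    }
                except DiffNetError:
                    test_doc = None  # all deltas zero: nothing to test
                out[tissue] = {"summary": summary, "wilcoxon": test_doc}
            return out

        conn = stage("diffnet", _diffnet)
        report["connectivity"] = {
            t: (
                None
                if doc is None
                else {
                    "n_gain": doc["summary"].n_gain,
                    "n_loss": doc["summary"].n_loss,
                    "n_unchanged": doc["summary"].n_unchanged,
                    "wilcoxon": doc["wilcoxon"],
                }
            )
            for t, doc in conn.items()
        }
        if len(tissues) == 2 and all(conn[t] is not None for t in tissues):
            ratios = cross_tissue_comparison(
                conn[tissues[0]]["summary"], conn[tissues[1]]["summary"]
            )
            report["cross_tissue"] = {
                "numerator": tissues[0],
                "denominator": tissues[1],
                "gain_ratio": ratios.gain_ratio,
                "loss_ratio": ratios.loss_ratio,
                "gain_undefined": ratios.gain_undefined,
                "loss_undefined": ratios.loss_undefined,
            }

        # -- enrichment ------------------------------------------------------
        enrichments: dict[str, pd.DataFrame] = {}
        if gene_sets is not None and len(gene_sets):

            def _enrich():
                out = {}
                for tissue, tbl in deg_tables.items():
                    universe = set(tbl.index)
                    for mode in ("all", "up", "down"):
                        try:
                            enr = fisher_enrichment(
                                tbl,
                                universe,
                                gene_sets,
                                direction_mode=mode,
                                p_threshold=config.p_enrich,
                                gate=config.enrichment_gate,
                            )
                        except EnrichmentError:
                            continue  # no DEGs in this direction
                        write_enrichment(enr, outdir / f"enrichment_{tissue}_{mode}.tsv")
                        out[(tissue, mode)] = enr
                return out

            enr_all = stage("enrichment", _enrich)
            report["enrichment"] = {
                f"{t}_{m}": {
                    "n_tested": int(len(enr)),
                    "n_enriched": int(enr["is_enriched"].sum()),
                    "enriched": sorted(enr.index[enr["is_enriched"]]),
                }
                for (t, m), enr in enr_all.items()
            }
            enrichments = {t: enr for (t, m), enr in enr_all.items() if m == "all"}

        # -- crosstalk network ----------------------------------------------
        report["crosstalk"] = None
        report["evaluation"] = None
        if enrichments:

            def _crosstalk():
                # union of per-tissue enrichment over the union DEG set
                frames = []
                for t, enr in enrichments.items():
                    frames.append(enr[enr["is_enriched"]])
                combined = pd.concat(frames)
                combined = combined[~combined.index.duplicated(keep="first")]
                if combined.empty:
                    return None
                all_degs = set().union(*deg_sets.values())
                # recompute hit lists against the union DEG set
                combined = combined.copy()
                combined["hit_genes"] = [
                    sorted(set(gene_sets[name]) & all_degs) for name in combined.index
                ]
                net = build_pathway_gene_network(
                    combined,
                    all_degs,
                    interactions=interactions,
                    count_interactions_in_degree=config.hprd_degree,
                )
                top_pw, top_genes = rank_top_degree(net, config.top_n)
                ct = find_crosstalk_genes(net, config.min_pathways)
                write_bipartite_sif(net, outdir / "crosstalk_network.sif")
                write_rankings(top_pw, top_genes, outdir / "rankings.tsv")
                return net, top_pw, top_genes, ct

            result = stage("crosstalk", _crosstalk)
            if result is not None:
                net, top_pw, top_genes, ct = result
                report["crosstalk"] = {
                    "n_pathway_nodes": len(net.pathway_nodes),
                    "n_gene_nodes": len(net.gene_nodes),
                    "n_membership_edges": len(net.membership_edges),
                    "n_interaction_edges": len(net.interaction_edges),
                    "top_pathways": [[n, d] for n, d in top_pw],
                    "top_genes": [[n, d] for n, d in top_genes],
                    "crosstalk_genes": {g: list(p) for g, p in ct.items()},
                }

                # -- candidate-gene evaluation -----------------------------
                def _evaluate():
                    genes = [n for n, _ in top_genes]
                    table = candidate_gene_table(harmonized, genes)
                    write_evaluation(table, outdir / "evaluation.tsv")
                    return table

                if report["crosstalk"]["top_genes"]:
                    table = stage("evaluate", _evaluate)
                    report["evaluation"] = {
                        g: {c: table.loc[g, c] for c in table.columns}
                        for g in table.index
                    }

        report = _jsonable(report)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return report
    finally:
        if log_handler in logger.handlers:
            logger.removeHandler(log_handler)
            log_handler.close()
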