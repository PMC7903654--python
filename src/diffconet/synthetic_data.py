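"""Seeded generator for two-tissue, two-condition expression studies.

The generator plants the statistical structure that the downstream analysis
is designed to detect:

* **Correlation modules** — each module shares a single latent factor; every
  member gene is ``sqrt(rho) * f + sqrt(1 - rho) * eps`` with ``f`` and
  ``eps`` independent standard normal draws, so the population pairwise
  correlation of two module genes is exactly ``rho``. Under the disease
  condition a chosen fraction of modules is *rewired*: their correlation
  drops to ``rho_disease``, producing connectivity loss in a thresholded
  co-expression network.
* **Differential expression** — a fraction of genes receives an additive
  mean shift in disease samples (up or down); two tissues share a stated
  fraction of their planted DE genes.
* **Batch structure** — every sample belongs to a batch and every
  (batch, gene) pair receives an additive offset, emulating the multi-series
  origin of merged public datasets.

Companion generators emit pathway gene sets overlapping the planted DE genes
and a gene-gene interaction map concentrated within modules, together with a
ground-truth record for recovery tests.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .harmonize import DISEASE, NORMAL, ExpressionDataset
from .pathway_crosstalk import GeneSets

UP = "up"
DOWN = "down"


class SynthConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic study.

    The defaults are the documented recovery preset: ten modules of twenty
    genes with within-module correlation 0.81 dropping to 0.25 in half the
    modules under disease, a quarter of genes differentially expressed with
    a one-standard-deviation shift, sixty samples per (tissue, condition)
    split over three batches, and half of the DE genes shared between the
    two tissues.
    """

    n_genes: int = 400
    n_modules: int = 10
    module_size: int = 20
    rho_normal: float = 0.81
    rho_disease: float = 0.25
    frac_rewired_modules: float = 0.5
    frac_de_genes: float = 0.25
    de_shift: float = 1.0
    n_samples_per_group: int = 60
    n_batches: int = 3
    batch_sd: float = 0.3
    shared_de_fraction: float = 0.5
    de_down_fraction: float = 0.5
    seed: int = 0
    tissues: tuple[str, str] = ("ACC", "PFC")
    alias_shared_genes: tuple[str, ...] = ()

    def validate(self) -> None:
        for name in ("n_genes", "n_modules", "module_size", "n_samples_per_group", "n_batches"):
            if int(getattr(self, name)) < 1:
                raise SynthConfigError(f"{name} must be >= 1")
        if self.n_modules * self.module_size > self.n_genes:
            raise SynthConfigError("n_modules * module_size exceeds n_genes")
        if not (0.0 <= self.rho_disease <= self.rho_normal < 1.0):
            raise SynthConfigError(
                "rho_disease/rho_normal must satisfy 0 <= rho_disease <= rho_normal < 1"
            )
        for name in (
            "frac_rewired_modules",
            "frac_de_genes",
            "shared_de_fraction",
            "de_down_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SynthConfigError(f"{name} must lie in [0, 1]")
        if self.batch_sd < 0:
            raise SynthConfigError("batch_sd must be >= 0")
        n_de = round(self.frac_de_genes * self.n_genes)
        n_shared = round(self.shared_de_fraction * n_de)
        if 2 * n_de - n_shared > self.n_genes:
            raise SynthConfigError(
                "frac_de_genes too large for disjoint tissue-specific DE sets"
            )


@dataclass
class SynthTruth:
    """Ground truth of a generated study.

    ``module_assignment`` maps module genes to their module id (background
    genes are absent); ``de_genes`` maps each tissue to ``gene -> direction``.
    """

    genes: list[str]
    module_assignment: dict[str, int]
    rewired_modules: set[int]
    de_genes: dict[str, dict[str, str]]
    shared_de_genes: set[str]

    def module_of(self, gene: str) -> int | None:
        return self.module_assignment.get(gene)

    def to_json(self, path) -> None:
        doc = {
            "genes": self.genes,
            "module_assignment": self.module_assignment,
            "rewired_modules": sorted(self.rewired_modules),
            "de_genes": self.de_genes,
            "shared_de_genes": sorted(self.shared_de_genes),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SynthTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            genes=list(doc["genes"]),
            module_assignment={g: int(m) for g, m in doc["module_assignment"].items()},
            rewired_modules=set(int(m) for m in doc["rewired_modules"]),
            de_genes={t: dict(d) for t, d in doc["de_genes"].items()},
            shared_de_genes=set(doc["shared_de_genes"]),
        )


# ---------------------------------------------------------------------------
# Expression generator
# ---------------------------------------------------------------------------


def _sample_frame(tissue: str, condition: str, n: int, n_batches: int) -> pd.DataFrame:
    ids = [f"{tissue}_{condition}_{i:03d}" for i in range(1, n + 1)]
    batches = [f"{tissue}_b{(i % n_batches) + 1}" for i in range(n)]
    return pd.DataFrame(
        {"condition": condition, "tissue": tissue, "batch": batches}, index=ids
    )


def generate_expression_pair(
    config: SynthConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, SynthTruth]:
    """Generate one expression dataset per tissue plus the ground truth.

    Deterministic given ``config`` (including its seed): two calls with the
    same configuration return bitwise-identical matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"G{i:06d}" for i in range(1, n + 1)]

    module_rows = {
        k: np.arange(k * config.module_size, (k + 1) * config.module_size)
        for k in range(config.n_modules)
    }
    n_rewired = round(config.frac_rewired_modules * config.n_modules)
    rewired = set(
        int(k) for k in rng.choice(config.n_modules, size=n_rewired, replace=False)
    )

    n_de = round(config.frac_de_genes * n)
    n_shared = round(config.shared_de_fraction * n_de)
    perm = rng.permutation(n)
    shared_idx = perm[:n_shared]
    extra = {
        config.tissues[0]: perm[n_shared:n_de],
        config.tissues[1]: perm[n_de : 2 * n_de - n_shared],
    }
    shared_dirs = np.where(rng.random(n_shared) < config.de_down_fraction, DOWN, UP)

    de_idx: dict[str, np.ndarray] = {}
    de_dirs: dict[str, np.ndarray] = {}
    for t in config.tissues:
        own_dirs = np.where(
            rng.random(len(extra[t])) < config.de_down_fraction, DOWN, UP
        )
        de_idx[t] = np.concatenate([shared_idx, extra[t]]).astype(int)
        de_dirs[t] = np.concatenate([shared_dirs, own_dirs])

    datasets = []
    for t in config.tissues:
        blocks, frames = [], []
        for condition in (NORMAL, DISEASE):
            ns = config.n_samples_per_group
            f = rng.standard_normal((config.n_modules, ns))
            eps = rng.standard_normal((n, ns))
            x = eps.copy()
            for k, rows in module_rows.items():
                rho = (
                    config.rho_disease
                    if (condition == DISEASE and k in rewired)
                    else config.rho_normal
                )
                x[rows] = np.sqrt(rho) * f[k] + np.sqrt(1.0 - rho) * eps[rows]
            if condition == DISEASE and len(de_idx[t]):
                signs = np.where(de_dirs[t] == UP, 1.0, -1.0)
                x[de_idx[t]] += signs[:, None] * config.de_shift
            blocks.append(x)
            frames.append(_sample_frame(t, condition, ns, config.n_batches))
        samples = pd.concat(frames)
        values = np.concatenate(blocks, axis=1)
        if config.batch_sd > 0:
            offsets = rng.normal(0.0, config.batch_sd, size=(config.n_batches, n))
            batch_index = np.array(
                [int(b.rsplit("b", 1)[1]) - 1 for b in samples["batch"]]
            )
            values = values + offsets[batch_index].T
        datasets.append(
            ExpressionDataset(
                values=pd.DataFrame(values, index=genes, columns=samples.index),
                samples=samples,
            )
        )

    gene_names = list(genes)
    if config.alias_shared_genes:
        # rename the first planted shared genes to narrative symbols
        aliases = dict(zip((genes[i] for i in shared_idx), config.alias_shared_genes))
        gene_names = [aliases.get(g, g) for g in genes]
        for ds in datasets:
            ds.values.index = pd.Index(gene_names)
        genes = gene_names

    module_assignment = {
        genes[i]: k for k, rows in module_rows.items() for i in rows
    }
    truth = SynthTruth(
        genes=list(genes),
        module_assignment=module_assignment,
        rewired_modules=rewired,
        de_genes={
            t: {genes[i]: d for i, d in zip(de_idx[t], de_dirs[t])}
            for t in config.tissues
        },
        shared_de_genes={genes[i] for i in shared_idx},
    )
    return datasets[0], datasets[1], truth


# ---------------------------------------------------------------------------
# Pathway fixture generator
# ---------------------------------------------------------------------------


@dataclass
class PathwayCollection:
    """Gene sets plus the ground truth of their enrichment status."""

    gene_sets: GeneSets
    enrichment_positive: set[str]
    crosstalk_genes: dict[str, tuple[str, ...]]
    tissue: str = ""  # whose DE pool seeded the positive pathways


def generate_pathway_gmt(
    truth: SynthTruth,
    n_pathways: int = 16,
    overlap_fraction: float = 0.8,
    seed: int = 0,
    pathway_size: int = 15,
    positive_fraction: float = 0.5,
    n_crosstalk_genes: int = 3,
    tissue: str | None = None,
) -> PathwayCollection:
    """Emit gene sets, a stated subset of which is enrichment-positive.

    Positive pathways draw ``overlap_fraction`` of their members from the
    planted DE genes of one tissue (default: the first tissue in `truth`),
    the remainder and all negative pathways from background genes. Member
    draws are disjoint across pathways except for ``n_crosstalk_genes``
    deliberately planted into two positive pathways each, so the crosstalk
    genes of the resulting network are known exactly.
    """
    if not truth.module_assignment:
        raise SynthConfigError("truth has no modules")
    if not (0.0 <= overlap_fraction <= 1.0):
        raise SynthConfigError("overlap_fraction must lie in [0, 1]")
    if n_pathways < 1:
        raise SynthConfigError("n_pathways must be >= 1")
    rng = np.random.default_rng(seed)
    tissue = tissue if tissue is not None else next(iter(truth.de_genes))
    de_all = sorted(truth.de_genes[tissue])
    bg_all = sorted(set(truth.genes) - set(de_all))

    n_pos = round(positive_fraction * n_pathways)
    pos_index = set(
        int(i) for i in rng.choice(n_pathways, size=n_pos, replace=False)
    )

    crosstalk: dict[str, tuple[str, ...]] = {}
    names = [f"PW{i:03d}" for i in range(1, n_pathways + 1)]
    pos_names = [names[i] for i in sorted(pos_index)]
    ct_genes: list[str] = []
    if n_pos >= 2 and n_crosstalk_genes > 0 and de_all:
        preferred = sorted(truth.shared_de_genes & set(de_all)) or de_all
        k = min(n_crosstalk_genes, len(preferred))
        ct_genes = [preferred[int(i)] for i in rng.choice(len(preferred), size=k, replace=False)]
        for j, g in enumerate(ct_genes):
            homes = (pos_names[j % n_pos], pos_names[(j + 1) % n_pos])
            crosstalk[g] = tuple(sorted(set(homes)))

    de_pool = [g for g in rng.permutation([g for g in de_all if g not in ct_genes])]
    bg_pool = [g for g in rng.permutation(bg_all)]

    def draw(pool: list[str], fallback: Sequence[str], k: int) -> list[str]:
        taken = []
        while len(taken) < k:
            if pool:
                taken.append(pool.pop())
            else:  # pool exhausted: reuse with replacement (loses disjointness)
                taken.append(fallback[int(rng.integers(len(fallback)))])
        return taken

    # without planted DE genes every pathway is background-only
    n_de_members = round(overlap_fraction * pathway_size) if de_all else 0
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    for i, name in enumerate(names):
        if i in pos_index:
            members = draw(de_pool, de_all, n_de_members)
            members += draw(bg_pool, bg_all, pathway_size - n_de_members)
        else:
            members = draw(bg_pool, bg_all, pathway_size)
        for g, homes in crosstalk.items():
            if name in homes:
                members.append(g)
        sets[name] = tuple(dict.fromkeys(members))
        descriptions[name] = "synthetic gene set"
    return PathwayCollection(
        gene_sets=GeneSets(sets=sets, descriptions=descriptions),
        enrichment_positive=set(pos_names),
        crosstalk_genes=crosstalk,
        tissue=tissue,
    )


# ---------------------------------------------------------------------------
# Interaction-map fixture generator
# ---------------------------------------------------------------------------


def generate_interaction_edges(
    truth: SynthTruth,
    density_within: float = 0.5,
    density_background: float = 0.005,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Undirected, deduplicated, self-loop-free gene-gene edge list.

    Pairs within the same planted module are included with probability
    ``density_within``, all other pairs with ``density_background``.
    """
    for name, v in (("density_within", density_within), ("density_background", density_background)):
        if not (0.0 <= v <= 1.0):
            raise SynthConfigError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = truth.genes
    module = np.array([truth.module_assignment.get(g, -1) for g in genes])
    iu, ju = np.triu_indices(len(genes), k=1)
    same = (module[iu] == module[ju]) & (module[iu] >= 0)
    prob = np.where(same, density_within, density_background)
    hit = rng.random(len(prob)) < prob
    return [(genes[i], genes[j]) for i, j in zip(iu[hit], ju[hit])]


# ---------------------------------------------------------------------------
# Documented presets
# ---------------------------------------------------------------------------


def recovery_preset(seed: int = 0) -> SynthConfig:
    """The documented rewiring + DE preset (the class defaults)."""
    return SynthConfig(seed=seed)


def null_preset(seed: int = 0) -> SynthConfig:
    """Recovery preset with rewiring and differential expression switched off."""
    return SynthConfig(
        frac_rewired_modules=0.0,
        frac_de_genes=0.0,
        de_shift=0.0,
        rho_disease=SynthConfig.rho_normal,
        seed=seed,
    )


def null_de_calibration_preset(seed: int = 0) -> SynthConfig:
    """Null config for marginal (per-gene test) calibration.

    Background-dominated (one token module of two genes), no batch offsets:
    gene-level tests are then independent draws from the null, so aggregate
    rejection rates obey binomial bounds exactly.
    """
    return SynthConfig(
        n_genes=300,
        n_modules=1,
        module_size=2,
        rho_normal=0.3,
        rho_disease=0.3,
        frac_rewired_modules=0.0,
        frac_de_genes=0.0,
        de_shift=0.0,
        n_batches=1,
        batch_sd=0.0,
        seed=seed,
    )


def null_network_calibration_preset(seed: int = 0) -> SynthConfig:
    """Null config for connectivity-test calibration.

    Modules sit moderately above the correlation threshold (rho = 0.55 in
    both conditions) so that thresholded networks exist in both conditions
    and per-gene degree differences are nonzero sampling noise.
    """
    return SynthConfig(
        n_genes=220,
        n_modules=10,
        module_size=20,
        rho_normal=0.55,
        rho_disease=0.55,
        frac_rewired_modules=0.0,
        frac_de_genes=0.0,
        de_shift=0.0,
        n_batches=1,
        batch_sd=0.0,
        seed=seed,
    )
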