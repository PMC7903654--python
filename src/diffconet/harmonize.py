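"""Probe collapsing, per-batch z-score standardization, and multi-batch merging.

Microarray studies of the same tissue are typically spread over several GEO
series measured on different platforms. Before any cross-sample statistic can
be computed the probe-level matrices must be collapsed to one row per gene,
each (gene, batch) slice must be brought to a common location/scale, and the
batches concatenated over their shared gene universe. This module provides
that harmonization path and the :class:`ExpressionDataset` container the rest
of the pipeline operates on.

Standardization is per (gene, batch): ``(x - mean) / sd`` with the sample
(n-1) standard deviation, which removes additive batch offsets and equalizes
variance across platforms without any cross-batch model fitting.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("diffconet")

#: condition labels used throughout the package
NORMAL = "normal"
DISEASE = "disease"

#: sample-metadata columns carried by every ExpressionDataset
SAMPLE_COLUMNS = ("condition", "tissue", "batch")

#: on-disk metadata dialect: the batch column is called "dataset"
_META_FILE_COLUMNS = {"condition": "condition", "tissue": "tissue", "batch": "dataset"}


class HarmonizeError(ValueError):
    """Raised for invalid harmonization inputs."""


@dataclass
class ExpressionDataset:
    """Gene-by-sample expression matrix with per-sample labels.

    Parameters
    ----------
    values
        DataFrame of expression values, index = gene symbols,
        columns = sample identifiers.
    samples
        DataFrame indexed by sample identifier with columns
        ``condition`` (``"normal"``/``"disease"``), ``tissue`` and ``batch``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()][:3].tolist()
            raise HarmonizeError(f"duplicate gene ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()][:3].tolist()
            raise HarmonizeError(f"duplicate sample ids: {dupes}")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise HarmonizeError(f"sample metadata lacks columns {missing}")
        if list(self.samples.index) != list(self.values.columns):
            raise HarmonizeError("sample metadata index does not match value columns")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def condition(self) -> pd.Series:
        return self.samples["condition"]

    @property
    def tissue(self) -> pd.Series:
        return self.samples["tissue"]

    @property
    def batch(self) -> pd.Series:
        return self.samples["batch"]

    def condition_values(self, condition: str) -> pd.DataFrame:
        """Columns of `values` belonging to one condition."""
        cols = self.samples.index[self.samples["condition"] == condition]
        return self.values[cols]

    # -- I/O (expression TSV + metadata TSV dialect) ---------------------------

    def to_tsv(self, expression_path, metadata_path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        # %.17g round-trips float64 exactly
        out.to_csv(expression_path, sep="\t", float_format="%.17g")
        meta = self.samples[list(SAMPLE_COLUMNS)].rename(columns=_META_FILE_COLUMNS)
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(cls, expression_path, metadata_path) -> "ExpressionDataset":
        values = pd.read_csv(
            expression_path, sep="\t", index_col=0, float_precision="round_trip"
        )
        values.index = values.index.astype(str)
        values.index.name = None
        values.columns.name = None
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
        meta.index = meta.index.astype(str)
        meta.index.name = None
        inv = {v: k for k, v in _META_FILE_COLUMNS.items()}
        meta = meta.rename(columns=inv)
        meta = meta.reindex(values.columns)
        return cls(values=values, samples=meta[list(SAMPLE_COLUMNS)])


def collapse_probes(
    probe_values: pd.DataFrame,
    probe_gene_map: Mapping[str, str] | pd.Series,
    samples: pd.DataFrame,
    mode: str = "max_mean",
) -> ExpressionDataset:
    """Collapse a probe-level matrix to one row per gene.

    ``mode="max_mean"`` keeps, per gene, the probe with the highest mean
    expression across samples (ties broken by lexicographically smallest
    probe id); ``mode="mean"`` averages all probes of a gene. Probes absent
    from the map are dropped (count logged).
    """
    if probe_values.shape[0] == 0 or probe_values.shape[1] == 0:
        raise HarmonizeError("empty probe matrix")
    if mode not in ("max_mean", "mean"):
        raise HarmonizeError(f"unknown collapse mode {mode!r}")
    mapping = pd.Series(dict(probe_gene_map)) if not isinstance(probe_gene_map, pd.Series) else probe_gene_map
    gene_of = probe_values.index.to_series().map(mapping)
    unmapped = int(gene_of.isna().sum())
    if unmapped:
        logger.info("collapse_probes: dropping %d unmapped probes", unmapped)
    keep = gene_of.notna()
    if not keep.any():
        raise HarmonizeError("all probes unmapped")
    pv = probe_values.loc[keep]
    genes = gene_of[keep]

    if mode == "mean":
        collapsed = pv.groupby(genes).mean()
    else:
        key = pd.DataFrame({"gene": genes, "mean": pv.mean(axis=1)})
        # lexicographic probe order first, then a stable sort by mean keeps
        # the smallest probe id on equal means
        key = key.sort_index(kind="mergesort")
        key = key.sort_values("mean", ascending=False, kind="mergesort")
        key = key.sort_values("gene", kind="mergesort")
        winners = key[~key["gene"].duplicated()]
        collapsed = pv.loc[winners.index]
        collapsed.index = winners["gene"]
    collapsed = collapsed.sort_index()
    collapsed.index.name = None
    return ExpressionDataset(values=collapsed, samples=samples.copy())


def zscore_standardize(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardize every (gene, batch) slice to mean 0, unit sample sd.

    Constant slices are mapped to all-zeros with a warning; a batch with a
    single sample is an error (its sample sd is undefined).
    """
    out = ds.values.astype(float).copy()
    n_const = 0
    for batch, meta in ds.samples.groupby("batch", sort=False):
        cols = meta.index
        if len(cols) < 2:
            raise HarmonizeError(f"batch {batch!r} has a single sample; cannot standardize")
        sub = out[cols]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        const = ~(sd > 0)
        z = sub.sub(mu, axis=0).div(sd.where(~const, 1.0), axis=0)
        if const.any():
            n_const += int(const.sum())
            z.loc[const] = 0.0
        out[cols] = z
    if n_const:
        warnings.warn(
            f"zscore_standardize: {n_const} constant (gene, batch) slices set to zero",
            UserWarning,
            stacklevel=2,
        )
    return ExpressionDataset(values=out, samples=ds.samples.copy())


def merge_datasets(
    datasets: Sequence[ExpressionDataset], tissue: str | None = None
) -> ExpressionDataset:
    """Concatenate standardized datasets over their shared gene universe.

    Genes absent from any input are dropped (count logged); batch labels are
    preserved. If `tissue` is given it overrides the per-sample tissue label.
    """
    if not datasets:
        raise HarmonizeError("no datasets to merge")
    common = datasets[0].values.index
    for ds in datasets[1:]:
        common = common.intersection(ds.values.index)
    # keep the gene order of the first dataset
    common = [g for g in datasets[0].gene_ids if g in set(common)]
    if not common:
        raise HarmonizeError("empty gene intersection across datasets")
    dropped = sum(len(ds.gene_ids) for ds in datasets) - len(common) * len(datasets)
    if dropped:
        logger.info("merge_datasets: %d gene rows dropped outside the intersection", dropped)
    values = pd.concat([ds.values.loc[common] for ds in datasets], axis=1)
    samples = pd.concat([ds.samples for ds in datasets], axis=0)
    if samples.index.duplicated().any():
        dupes = samples.index[samples.index.duplicated()][:3].tolist()
        raise HarmonizeError(f"duplicate sample ids across datasets: {dupes}")
    if tissue is not None:
        samples = samples.copy()
        samples["tissue"] = tissue
    return ExpressionDataset(values=values, samples=samples)


def read_probe_map(path) -> pd.Series:
    """Two-column TSV (probe_id, gene_symbol) -> Series probe -> gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise HarmonizeError("probe map needs two columns: probe_id, gene_symbol")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def write_probe_map(mapping: Mapping[str, str], path) -> None:
    df = pd.DataFrame(
        {"probe_id": list(mapping.keys()), "gene_symbol": list(mapping.values())}
    )
    df.to_csv(path, sep="\t", index=False)
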