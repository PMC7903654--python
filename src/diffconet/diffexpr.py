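"""Differential expression between disease and control samples.

Each gene is tested with Welch's unequal-variance two-sample t-test on the
standardized expression values. Because the data are z-scored, a literal
fold change is undefined; the reported ``effect`` is the difference of group
means (disease minus control) in standardized units and serves as the
log-fold-change surrogate. A gene is called differentially expressed when
its raw p-value passes the threshold and its absolute effect exceeds the
(default zero) effect threshold; Benjamini-Hochberg adjusted p-values are
reported alongside but do not drive the call.
"""
from __future__ import annotations

import json
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .harmonize import DISEASE, NORMAL, ExpressionDataset


class DiffExprError(ValueError):
    """Raised for invalid differential-expression inputs."""


def gene_stat(case_values, control_values) -> tuple[float, float, float]:
    """Welch two-sample test for one gene.

    Returns ``(effect, t, p)`` with ``effect = mean(case) - mean(control)``
    and a two-sided p-value. Groups with fewer than three samples are
    rejected; two zero-variance groups with equal means give ``p = 1``.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 3 or control.size < 3:
        raise DiffExprError("each group needs at least 3 samples")
    effect = float(case.mean() - control.mean())
    if case.var(ddof=1) == 0.0 and control.var(ddof=1) == 0.0:
        if effect == 0.0:
            return 0.0, 0.0, 1.0
        return effect, float(np.sign(effect)) * np.inf, 0.0
    t, p = stats.ttest_ind(case, control, equal_var=False)
    return effect, float(t), float(p)


def call_degs(
    ds: ExpressionDataset, p_threshold: float = 0.05, effect_threshold: float = 0.0
) -> pd.DataFrame:
    """Per-gene DEG table for one tissue.

    Returns a DataFrame indexed by gene with columns
    ``effect, t, p, p_adj, direction, is_deg``.
    """
    case = ds.condition_values(DISEASE).to_numpy(dtype=float)
    control = ds.condition_values(NORMAL).to_numpy(dtype=float)
    if case.shape[1] == 0 or control.shape[1] == 0:
        raise DiffExprError("dataset must contain both conditions")
    if case.shape[1] < 3 or control.shape[1] < 3:
        raise DiffExprError("each condition needs at least 3 samples")
    effect = case.mean(axis=1) - control.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, control, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = (case.var(axis=1, ddof=1) == 0.0) & (control.var(axis=1, ddof=1) == 0.0)
    same = degenerate & (effect == 0.0)
    diff = degenerate & (effect != 0.0)
    t[same], p[same] = 0.0, 1.0
    t[diff], p[diff] = np.sign(effect[diff]) * np.inf, 0.0
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "effect": effect,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(effect > 0, "up", "down"),
            "is_deg": (p < p_threshold) & (np.abs(effect) > effect_threshold),
        },
        index=ds.values.index,
    )
    return table


def deg_genes(table: pd.DataFrame) -> set[str]:
    """Genes flagged as DEGs in a DEG table."""
    return set(table.index[table["is_deg"]])


def deg_overlap(set_a: Iterable[str], set_b: Iterable[str]) -> tuple[int, int, int]:
    """Venn partition counts ``(only_a, shared, only_b)``."""
    a, b = set(set_a), set(set_b)
    shared = len(a & b)
    return len(a) - shared, shared, len(b) - shared


def write_deg_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    df["is_deg"] = df["is_deg"].astype(bool)
    return df


def write_overlap(counts: tuple[int, int, int], path) -> None:
    only_a, shared, only_b = counts
    with open(path, "w") as fh:
        json.dump({"only_a": only_a, "shared": shared, "only_b": only_b}, fh, indent=2)
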