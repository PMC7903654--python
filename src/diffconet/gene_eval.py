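"""Candidate-gene evaluation: group comparison and single-gene ROC.

Each candidate gene is scored in each tissue by (i) a Welch two-sided test
of disease versus control expression, Benjamini-Hochberg corrected within
the evaluated gene family per tissue, and (ii) the area under the ROC curve
with the gene's expression as the classifier score for disease versus
control. The AUC is the Mann-Whitney concordance probability
U / (n1 * n2), where U counts (case, control) pairs with the case scoring
higher plus half the ties; ``auc_oriented`` folds below-chance values to
max(auc, 1 - auc).
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffexpr import gene_stat
from .harmonize import DISEASE, NORMAL, ExpressionDataset


class GeneEvalError(ValueError):
    """Raised for invalid gene-evaluation inputs."""


def gene_auc(scores_case, scores_control) -> tuple[float, float]:
    """(auc, auc_oriented) from the Mann-Whitney construction."""
    case = np.asarray(scores_case, dtype=float)
    control = np.asarray(scores_control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise GeneEvalError("both groups must be nonempty")
    ranks = stats.rankdata(np.concatenate([case, control]))
    u = ranks[: case.size].sum() - case.size * (case.size + 1) / 2.0
    auc = float(u / (case.size * control.size))
    return auc, max(auc, 1.0 - auc)


def candidate_gene_table(
    datasets: Mapping[str, ExpressionDataset], genes: Sequence[str]
) -> pd.DataFrame:
    """Per gene x tissue p-values (raw and BH-corrected) and AUCs.

    ``datasets`` maps tissue label to its harmonized dataset; every listed
    gene must be present in every dataset. Rows keep the input gene order;
    columns are ``p_<tissue>, p_corrected_<tissue>, auc_<tissue>,
    auc_oriented_<tissue>`` per tissue.
    """
    if not genes:
        raise GeneEvalError("empty gene list")
    out = pd.DataFrame(index=list(genes))
    for tissue, ds in datasets.items():
        missing = [g for g in genes if g not in ds.values.index]
        if missing:
            raise GeneEvalError(f"gene {missing[0]!r} not in {tissue} dataset")
        case = ds.condition_values(DISEASE)
        control = ds.condition_values(NORMAL)
        p_raw, aucs, oriented = [], [], []
        for g in genes:
            _, _, p = gene_stat(case.loc[g].to_numpy(), control.loc[g].to_numpy())
            a, ao = gene_auc(case.loc[g].to_numpy(), control.loc[g].to_numpy())
            p_raw.append(p)
            aucs.append(a)
            oriented.append(ao)
        out[f"p_{tissue}"] = p_raw
        out[f"p_corrected_{tissue}"] = multipletests(p_raw, method="fdr_bh")[1]
        out[f"auc_{tissue}"] = aucs
        out[f"auc_oriented_{tissue}"] = oriented
    return out


def write_evaluation(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_evaluation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df
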