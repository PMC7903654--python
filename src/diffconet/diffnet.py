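"""Per-gene connectivity change between normal and disease networks.

For every gene in the shared universe of a condition pair, the degree under
each condition is looked up (zero if isolated) and the difference classified
as gain, loss, or unchanged. The paired difference in connectivity is tested
with the Wilcoxon signed-rank test: zero differences are dropped
(Wilcoxon's procedure; Pratt's available via flag), absolute differences are
midranked on ties, and the null distribution of the positive-rank sum W is
computed exactly (by dynamic programming over sign assignments) up to 25
effective pairs, otherwise by the tie-corrected normal approximation with
continuity correction. Gain/loss summaries of two tissues are compared as
ratios.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .coexpr_network import CoexpressionNetwork


class DiffNetError(ValueError):
    """Raised for invalid connectivity comparisons."""


class GainLoss(NamedTuple):
    n_gain: int
    n_loss: int
    n_unchanged: int


@dataclass
class ConnectivityTest:
    statistic: float
    n_effective: int
    p: float
    method: str


@dataclass
class CrossTissueRatios:
    gain_ratio: float
    loss_ratio: float
    gain_undefined: bool = False
    loss_undefined: bool = False


def connectivity_delta(
    net_normal: CoexpressionNetwork, net_disease: CoexpressionNetwork
) -> pd.DataFrame:
    """Per-gene degrees under both conditions with gain/loss status.

    The shared universe is the intersection of the two networks' universes
    (in the normal network's order); genes isolated in a network count with
    degree zero there.
    """
    disease_universe = set(net_disease.universe)
    shared = [g for g in net_normal.universe if g in disease_universe]
    if not shared:
        raise DiffNetError("networks have disjoint universes")
    deg_n = np.array([net_normal.degree_of(g) for g in shared], dtype=int)
    deg_d = np.array([net_disease.degree_of(g) for g in shared], dtype=int)
    delta = deg_d - deg_n
    status = np.where(delta > 0, "gain", np.where(delta < 0, "loss", "unchanged"))
    return pd.DataFrame(
        {
            "degree_normal": deg_n,
            "degree_disease": deg_d,
            "delta": delta,
            "status": status,
        },
        index=shared,
    )


def gain_loss_summary(deltas: pd.DataFrame) -> GainLoss:
    """Disjoint counts of gain/loss/unchanged genes."""
    d = deltas["delta"].to_numpy()
    return GainLoss(int((d > 0).sum()), int((d < 0).sum()), int((d == 0).sum()))


def _exact_signed_rank_p(ranks: np.ndarray, w: float) -> float:
    """Two-sided exact p for the positive-rank sum under random signs.

    Midranks are doubled to integers; the null distribution of 2W is built
    by convolution over the 2^n equally likely sign assignments.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(np.rint(2.0 * w))
    lower = float(dist[: w2 + 1].sum())
    upper = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def signed_rank_test(deltas, exact_limit: int = 25) -> ConnectivityTest:
    """Wilcoxon signed-rank test on a vector of paired differences.

    Zeros are dropped first; an all-zero vector is a degenerate pairing.
    The statistic is W, the sum of the (mid)ranks of positive differences.
    """
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DiffNetError("degenerate pairing: all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_limit:
        return ConnectivityTest(w, n, _exact_signed_rank_p(ranks, w), "exact")
    mu = n * (n + 1) / 4.0
    # tie correction over groups of tied |delta|
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts) / 48.0).sum())
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return ConnectivityTest(w, n, 1.0, "approx")
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return ConnectivityTest(w, n, p, "approx")


def connectivity_wilcoxon(
    deltas: pd.DataFrame,
    paired: bool = True,
    zero_method: str = "wilcox",
    exact_limit: int = 25,
) -> ConnectivityTest:
    """Test the per-gene connectivity difference between conditions.

    Default: paired signed-rank on (degree_normal, degree_disease) with
    zero differences dropped. ``zero_method="pratt"`` keeps zeros in the
    ranking (delegated to scipy); ``paired=False`` runs the unpaired
    Mann-Whitney rank-sum test on the two degree vectors instead.
    """
    deg_n = deltas["degree_normal"].to_numpy(dtype=float)
    deg_d = deltas["degree_disease"].to_numpy(dtype=float)
    if not paired:
        res = stats.mannwhitneyu(deg_d, deg_n, alternative="two-sided")
        return ConnectivityTest(float(res.statistic), len(deg_n), float(res.pvalue), "rank-sum")
    d = deg_d - deg_n
    if zero_method == "pratt":
        if not np.any(d):
            raise DiffNetError("degenerate pairing: all differences are zero")
        res = stats.wilcoxon(
            d, zero_method="pratt", correction=True, alternative="two-sided", method="approx"
        )
        n_eff = int(np.count_nonzero(d))
        return ConnectivityTest(float(res.statistic), n_eff, float(res.pvalue), "pratt-approx")
    if zero_method != "wilcox":
        raise DiffNetError(f"unknown zero_method {zero_method!r}")
    return signed_rank_test(d, exact_limit=exact_limit)


def cross_tissue_comparison(summary_a: GainLoss, summary_b: GainLoss) -> CrossTissueRatios:
    """Gain and loss ratios between two tissues (numerator = first argument).

    A zero denominator yields an infinite (or, for 0/0, NaN) ratio with the
    corresponding flag set.
    """
    if sum(summary_a) == 0 or sum(summary_b) == 0:
        raise DiffNetError("empty gain/loss summary")

    def ratio(a: int, b: int) -> tuple[float, bool]:
        if b == 0:
            return (np.nan, True) if a == 0 else (np.inf, True)
        return a / b, False

    gain, gflag = ratio(summary_a.n_gain, summary_b.n_gain)
    loss, lflag = ratio(summary_a.n_loss, summary_b.n_loss)
    return CrossTissueRatios(gain, loss, gflag, lflag)


def write_deltas(deltas: pd.DataFrame, path) -> None:
    out = deltas.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_deltas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df
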