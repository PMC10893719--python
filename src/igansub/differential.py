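"""Differential expression screens and gene-trait correlation.

The case-control and subtype-vs-rest contrasts share one engine: per-gene
log2 fold change as a difference of group means (the data arrive on the
log2 scale), a Welch two-sample t test, and Benjamini-Hochberg adjustment
across all tested genes.  Subtype-specific genes are the intersection of
the global DEG list with a subtype-vs-rest DEG list, with direction taken
from the subtype contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import UNASSIGNED


@dataclass(frozen=True)
class DEGThresholds:
    """Adjusted-p and |log2FC| cutoffs for a DEG screen."""

    alpha: float = 0.05
    lfc: float = 1.7

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.lfc < 0:
            raise ValueError("lfc must be >= 0")


#: thresholds of the per-subtype contrasts (subtype 1, 2, 3): progressively
#: looser |log2FC| cutoffs balance the feature counts across subtypes
SUBTYPE_THRESHOLDS = {
    1: DEGThresholds(0.01, 2.0),
    2: DEGThresholds(0.01, 1.5),
    3: DEGThresholds(0.01, 1.2),
}


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    adj_p[i] = min over j with p[j] >= p[i] of p[j] * n / rank(j), capped
    at 1; monotone in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def _welch_table(expr: pd.DataFrame, cols1: Sequence[str], cols2: Sequence[str]
                 ) -> pd.DataFrame:
    a = expr[list(cols1)].to_numpy(float)
    b = expr[list(cols2)].to_numpy(float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance degenerate genes
    return pd.DataFrame({
        "gene_id": expr.index,
        "log2fc": lfc,
        "p": p,
        "adj_p": bh_adjust(p),
    })


def two_group_degs(expr: pd.DataFrame, labels: Sequence[str],
                   thr: DEGThresholds,
                   group1: str | None = None,
                   group2: str | None = None) -> pd.DataFrame:
    """DEGs between two groups of samples.

    ``labels`` aligns with expr columns and must have exactly two levels;
    log2fc = mean(group1) - mean(group2) (group order defaults to first
    appearance).  p from Welch's t, BH-adjusted over all genes; rows with
    adj_p < alpha and |log2fc| > lfc are returned sorted by p (ties broken
    by gene id).
    """
    labels = pd.Series(list(labels), index=expr.columns)
    levels = list(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {levels}")
    g1 = group1 if group1 is not None else levels[0]
    g2 = group2 if group2 is not None else next(l for l in levels if l != g1)
    cols1 = labels.index[labels == g1]
    cols2 = labels.index[labels == g2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("each group needs at least 2 samples")

    tab = _welch_table(expr, cols1, cols2)
    keep = (tab["adj_p"] < thr.alpha) & (tab["log2fc"].abs() > thr.lfc)
    out = tab.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out = out.sort_values(["p", "gene_id"], kind="mergesort").reset_index(drop=True)
    return out


def subtype_vs_rest_degs(expr: pd.DataFrame, subtype_labels: Sequence[int],
                         target_subtype: int, thr: DEGThresholds) -> pd.DataFrame:
    """DEGs between one subtype's cases and all other assigned cases.

    Unassigned samples (label 0) are excluded from the contrast.
    """
    labels = pd.Series(list(subtype_labels), index=expr.columns)
    assigned = labels.index[labels != UNASSIGNED]
    labels = labels.loc[assigned]
    if target_subtype not in set(labels):
        raise ValueError(f"unknown subtype {target_subtype!r}")
    groups = np.where(labels == target_subtype, "target", "rest")
    return two_group_degs(expr[assigned], groups, thr,
                          group1="target", group2="rest")


def subtype_specific_genes(global_degs: pd.DataFrame,
                           subtype_degs: pd.DataFrame) -> pd.DataFrame:
    """Intersection of the global and subtype-vs-rest DEG lists.

    Returns gene_id + direction, with direction taken from the subtype
    contrast (the same gene may point different ways in different
    contrasts; reconciliation is left to the caller).
    """
    common = set(global_degs["gene_id"]) & set(subtype_degs["gene_id"])
    out = subtype_degs.loc[subtype_degs["gene_id"].isin(common),
                           ["gene_id", "log2fc", "direction"]]
    return out.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def gene_trait_correlation(expr: pd.DataFrame, trait: pd.Series,
                           genes: Sequence[str] | None = None,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each gene with a clinical trait.

    BH adjustment is applied over the supplied gene subset; a gene is
    flagged significant at adj_p < alpha.
    """
    trait = trait.dropna()
    common = [c for c in expr.columns if c in trait.index]
    if len(common) < 3:
        raise ValueError("need at least 3 paired observations")
    y = trait.loc[common].to_numpy(float)
    if np.std(y) == 0:
        raise ValueError("trait is constant")
    genes = list(genes) if genes is not None else list(expr.index)
    rows = []
    for g in genes:
        x = expr.loc[g, common].to_numpy(float)
        if np.std(x) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(x, y)
        rows.append((g, r, p))
    out = pd.DataFrame(rows, columns=["gene_id", "r", "p"])
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["adj_p"] < alpha
    return out
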