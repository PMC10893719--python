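"""Signature-based immune-cell fraction estimation and group comparisons.

Fractions are estimated per bulk sample by nonnegative least squares of
the shared-gene expression vector against the signature's cell-type
columns, renormalized onto the simplex.  (A support-vector variant of this
regression is common for noisy clinical mixtures; the NNLS estimator used
here is deterministic and exact on noise-free mixtures.)

Group comparisons per cell type use the Kruskal-Wallis test across all
groups and Wilcoxon rank-sum tests for each group against the control,
with BH adjustment within each test family and star annotation bins.
"""

from __future__ import annotations

import logging
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .differential import bh_adjust

log = logging.getLogger(__name__)


def estimate_fractions(bulk: pd.DataFrame, signature: pd.DataFrame,
                       ) -> pd.DataFrame:
    """Cell-type fractions per bulk sample (samples x cell types).

    Solves min ||S w - y||, w >= 0 over the genes shared between bulk and
    signature, then renormalizes w to sum 1.  An all-zero solution falls
    back to the uniform vector with a warning.
    """
    if signature.shape[1] < 2:
        raise ValueError("signature needs at least 2 cell types")
    if (signature.to_numpy() < 0).any():
        raise ValueError("signature must be nonnegative")
    shared = [g for g in signature.index if g in bulk.index]
    if len(shared) < signature.shape[1]:
        raise ValueError("fewer shared genes than cell types")
    S = signature.loc[shared].to_numpy(float)
    Y = bulk.loc[shared].to_numpy(float)
    out = np.zeros((bulk.shape[1], signature.shape[1]))
    for j in range(bulk.shape[1]):
        w, _ = nnls(S, Y[:, j])
        total = w.sum()
        if total <= 0:
            log.warning("estimate_fractions: all-zero solution for sample "
                        "%s; using uniform fractions", bulk.columns[j])
            w = np.full(signature.shape[1], 1.0 / signature.shape[1])
        else:
            w = w / total
        out[j] = w
    return pd.DataFrame(out, index=bulk.columns,
                        columns=list(signature.columns))


def _stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _ranksum(a: np.ndarray, b: np.ndarray, method: str) -> float:
    """Two-sided Wilcoxon rank-sum p.

    method "auto": exact when both groups have <= 25 observations and no
    ties, else normal approximation with continuity correction;
    "asymptotic": normal approximation without continuity correction (so
    that z^2 equals the two-group Kruskal-Wallis statistic exactly).
    """
    if method == "asymptotic":
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        return float(res.pvalue)
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if not ties and len(a) <= 25 and len(b) <= 25:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def compare_fractions(fractions: pd.DataFrame, groups: Sequence[str],
                      control: str | None = None,
                      method: str = "auto") -> pd.DataFrame:
    """Per-cell-type group tests on estimated fractions.

    Rows: one per cell type for the Kruskal-Wallis test over all groups
    (``group`` column "all"), plus one per (cell type, non-control group)
    for the rank-sum test of that group against the control.  BH is
    applied within each family; stars bin the adjusted p-values.
    """
    groups = pd.Series(list(groups), index=fractions.index)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 samples")
    if control is None:
        control = levels[-1]
    if control not in levels:
        raise ValueError(f"unknown control group {control!r}")

    kw_rows, pw_rows = [], []
    for cell in fractions.columns:
        arrays = [fractions.loc[groups == lev, cell].to_numpy(float)
                  for lev in levels]
        if np.ptp(np.concatenate(arrays)) == 0:
            h, p_kw = 0.0, 1.0
        else:
            h, p_kw = stats.kruskal(*arrays)
        kw_rows.append((cell, "all", "kruskal", float(h), float(p_kw)))
        ctrl_vals = fractions.loc[groups == control, cell].to_numpy(float)
        for lev in levels:
            if lev == control:
                continue
            vals = fractions.loc[groups == lev, cell].to_numpy(float)
            p = _ranksum(vals, ctrl_vals, method)
            pw_rows.append((cell, str(lev), "ranksum", float("nan"), p))

    out = pd.DataFrame(kw_rows + pw_rows,
                       columns=["cell_type", "group", "test", "stat", "p"])
    out["adj_p"] = np.nan
    for fam in ("kruskal", "ranksum"):
        mask = out["test"] == fam
        if mask.any():
            out.loc[mask, "adj_p"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out["stars"] = out["adj_p"].map(_stars)
    return out


def fraction_correlations(fractions: pd.DataFrame,
                          ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation between cell-type fractions.

    Returns (r, p) matrices; constant columns yield r = 0, p = 1 against
    every partner, with a warning.
    """
    if fractions.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    cells = list(fractions.columns)
    r = pd.DataFrame(np.eye(len(cells)), index=cells, columns=cells)
    p = pd.DataFrame(np.zeros((len(cells), len(cells))), index=cells,
                     columns=cells)
    const = [c for c in cells if np.std(fractions[c].to_numpy(float)) == 0]
    if const:
        log.warning("fraction_correlations: constant cell types %s", const)
    for i, ci in enumerate(cells):
        for j in range(i + 1, len(cells)):
            cj = cells[j]
            if ci in const or cj in const:
                rr, pp = 0.0, 1.0
            else:
                rr, pp = stats.pearsonr(fractions[ci].to_numpy(float),
                                        fractions[cj].to_numpy(float))
            r.loc[ci, cj] = r.loc[cj, ci] = rr
            p.loc[ci, cj] = p.loc[cj, ci] = pp
    return r, p
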