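"""Weighted gene co-expression network analysis.

An unsigned network: the adjacency between genes i and j is
``a_ij = |cor(x_i, x_j)|^beta`` with the soft-threshold exponent beta
chosen as the smallest power whose connectivity distribution fits a
scale-free law with signed R^2 at or above a target (default 0.9).
Adjacency is transformed to the standard unsigned topological overlap
matrix (TOM); modules are branches of an average-linkage tree on 1 - TOM,
cut at the static height that yields the most branches of admissible size
(a deliberate, documented simplification of hybrid dynamic tree cutting).
Module eigengenes are first principal components of the standardized
module submatrix; similar modules (eigengene correlation above
1 - cut_height) are merged iteratively.  Hub genes require both high
module membership (|MM| > 0.7) and high gene significance (|GS| > 0.2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

log = logging.getLogger(__name__)

GREY = "grey"

#: deterministic palette assigned to modules by decreasing size
_PALETTE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
    "darkred", "darkgreen", "darkturquoise", "darkgrey", "orange",
    "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


def variance_filter(expr: pd.DataFrame, top_frac: float = 0.25) -> pd.DataFrame:
    """Keep the ceil(top_frac * n_genes) genes of largest sample variance.

    Ties are broken by gene id; the retained genes keep their original
    matrix order.
    """
    if not (0 < top_frac <= 1):
        raise ValueError("top_frac must be in (0, 1]")
    n_keep = math.ceil(top_frac * expr.shape[0])
    var = expr.var(axis=1, ddof=1)
    order = sorted(expr.index, key=lambda g: (-var[g], g))
    keep = set(order[:n_keep])
    return expr.loc[[g for g in expr.index if g in keep]]


def adjacency_matrix(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency a_ij = |cor(x_i, x_j)|^beta with unit diagonal."""
    x = expr.to_numpy(float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x)
    bad = ~np.isfinite(corr)
    if bad.any():
        log.warning("adjacency: %d undefined correlations set to 0",
                    int(bad.sum()))
        corr = np.where(bad, 0.0, corr)
    a = np.abs(corr) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log scale-free topology fit.

    Connectivity is binned into ``n_bins`` equal-width bins; the fit
    regresses log10(frequency per bin) on log10(mean connectivity per bin)
    over nonempty bins and returns -sign(slope) * R^2, so a genuinely
    decaying (scale-free) degree distribution scores positively.
    """
    k = np.asarray(connectivity, dtype=float)
    if np.ptp(k) == 0:
        raise ValueError("constant connectivity")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k <= 0 or freq <= 0:
            continue
        xs.append(math.log10(mean_k))
        ys.append(math.log10(freq))
    if len(xs) < 3:
        raise ValueError("too few populated bins for the scale-free fit")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r ** 2)


def pick_soft_threshold(expr: pd.DataFrame,
                        powers: Sequence[int] = tuple(range(1, 21)),
                        r2_target: float = 0.9,
                        n_bins: int = 10) -> Tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free fit reaches ``r2_target``.

    Falls back (with a warning) to the argmax power when no power reaches
    the target.  Returns the chosen beta and the per-power fit table.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr.to_numpy(float)
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(x))
    corr = np.where(np.isfinite(corr), corr, 0.0)
    np.fill_diagonal(corr, 0.0)  # self-edges excluded from connectivity
    rows = []
    for power in powers:
        a = corr ** power
        k = a.sum(axis=1)
        try:
            r2 = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            log.warning("pick_soft_threshold: power %d skipped", power)
            continue
        rows.append((power, r2, float(k.mean()), float(np.median(k)),
                     float(k.max())))
    table = pd.DataFrame(rows, columns=["power", "signed_r2", "mean_k",
                                        "median_k", "max_k"])
    if table.empty:
        raise ValueError("no power admitted a scale-free fit")
    ok = table.loc[table["signed_r2"] >= r2_target]
    if len(ok):
        beta = int(ok["power"].iloc[0])
    else:
        beta = int(table.loc[table["signed_r2"].idxmax(), "power"])
        log.warning("pick_soft_threshold: target R2 %.2f unmet; using "
                    "argmax power %d", r2_target, beta)
    return beta, table


def tom_transform(adjacency: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, where
    L_ij = sum_u a_iu * a_uj over u != i, j and k_i = sum_u!=i a_iu; the
    diagonal is set to 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    diag = np.diag(a).copy()
    k = a.sum(axis=1) - diag
    m = a @ a
    # remove the u = i and u = j terms from the path count
    l_mat = m - diag[:, None] * a - a * diag[None, :]
    denom = np.minimum.outer(k, k) + 1.0 - a
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    tom = (l_mat + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class ModuleSet:
    """Gene -> module coloring with eigengenes and hub tables."""

    labels: pd.Series  # gene id -> color, "grey" = unassigned
    eigengenes: pd.DataFrame | None = None  # modules x samples
    mm: pd.DataFrame | None = None  # genes x modules correlations
    gs: pd.Series | None = None  # gene -> trait correlation
    hubs: Dict[str, List[str]] = field(default_factory=dict)

    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()


def _color_names(n: int) -> List[str]:
    names = list(_PALETTE)
    while len(names) < n:
        names.append(f"module_{len(names)}")
    return names[:n]


def detect_modules(tom: np.ndarray, gene_ids: Sequence[str],
                   min_module_size: int = 30) -> ModuleSet:
    """Modules as branches of an average-linkage tree on 1 - TOM.

    The tree is cut at a static height maximizing the number of branches
    with >= min_module_size genes.  Among tied heights, the cut is placed
    at the top of the *first* contiguous band achieving the maximum:
    within that band branches only accrete peripheral genes, so the cut
    captures complete modules just before they agglomerate with background
    or with each other (later bands at the same count are loose
    agglomerates).  Undersized branches become "grey".  Colors
    are assigned by decreasing module size, so the partition is invariant
    to gene order up to labels.
    """
    n = len(gene_ids)
    if tom.shape != (n, n):
        raise ValueError("tom shape does not match gene_ids")
    if n < min_module_size:
        log.warning("detect_modules: fewer genes than min_module_size; all grey")
        return ModuleSet(labels=pd.Series(GREY, index=list(gene_ids)))
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    Z = linkage(squareform(d, checks=False), method="average")
    heights = np.unique(Z[:, 2])
    mids = (heights[:-1] + heights[1:]) / 2.0
    candidates = np.concatenate([[heights[0] / 2.0], mids,
                                 [heights[-1] + 1.0]])
    cuts = []
    for h in candidates:
        labs = fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(labs)
        admissible = [c for c in np.unique(labs) if sizes[c] >= min_module_size]
        cuts.append((h, labs, admissible))
    counts = np.array([len(adm) for _, _, adm in cuts])
    max_count = counts.max()
    first = int(np.argmax(counts == max_count))
    last = first
    while last + 1 < len(cuts) and counts[last + 1] == max_count:
        last += 1
    h, labs, admissible = cuts[last]
    sizes = np.bincount(labs)
    ordered = sorted(admissible, key=lambda c: (-sizes[c], c))
    colors = _color_names(len(ordered))
    color_of = {c: colors[i] for i, c in enumerate(ordered)}
    labels = pd.Series([color_of.get(c, GREY) for c in labs],
                       index=list(gene_ids))
    return ModuleSet(labels=labels)


def module_eigengene(expr: pd.DataFrame, module_genes: Sequence[str]) -> pd.Series:
    """First principal component of the gene-standardized module submatrix.

    Scaled to unit sample variance; the sign is fixed so the eigengene
    correlates nonnegatively with the module's mean standardized profile.
    """
    genes = [g for g in module_genes if g in expr.index]
    if len(genes) < 2:
        raise ValueError("module needs at least 2 genes")
    x = expr.loc[genes].to_numpy(float)
    m = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd < 1e-8, 1e-8, sd)
    xs = (x - m) / sd
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    if s[0] < 1e-12:
        raise ValueError("rank-0 module submatrix")
    e = vt[0]
    mean_profile = xs.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    e = e / e.std(ddof=1)
    return pd.Series(e, index=expr.columns)


def compute_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """modules x samples eigengene matrix (grey excluded)."""
    modules = [mname for mname in labels.unique() if mname != GREY]
    rows = {}
    for mname in modules:
        rows[mname] = module_eigengene(expr, labels.index[labels == mname])
    return pd.DataFrame(rows).T


def merge_modules(expr: pd.DataFrame, labels: pd.Series,
                  cut_height: float = 0.25,
                  max_rounds: int = 20) -> Tuple[pd.Series, pd.DataFrame]:
    """Merge modules whose eigengenes correlate above 1 - cut_height.

    Average-linkage clustering of eigengenes on 1 - cor; branches below
    the cut height collapse into the largest member's label.  Iterates
    until stable; never increases the module count.
    """
    labels = labels.copy()
    for _ in range(max_rounds):
        eig = compute_eigengenes(expr, labels)
        if len(eig) <= 1:
            return labels, eig
        d = 1.0 - np.corrcoef(eig.to_numpy(float))
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        Z = linkage(squareform(d, checks=False), method="average")
        groups = fcluster(Z, t=cut_height, criterion="distance")
        if len(np.unique(groups)) == len(eig):
            return labels, eig
        sizes = labels.value_counts()
        for g in np.unique(groups):
            members = [eig.index[i] for i in np.flatnonzero(groups == g)]
            if len(members) < 2:
                continue
            target = max(members, key=lambda mname: (sizes.get(mname, 0), mname))
            labels = labels.replace({mname: target for mname in members})
    return labels, compute_eigengenes(expr, labels)


def module_trait_correlation(eigengenes: pd.DataFrame, traits: pd.DataFrame,
                             ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation (and two-sided p) of each eigengene with each
    trait column; subtype indicators should be passed one-vs-rest binary."""
    common = [c for c in eigengenes.columns if c in traits.index]
    r = pd.DataFrame(index=eigengenes.index, columns=traits.columns, dtype=float)
    p = r.copy()
    for mname in eigengenes.index:
        e = eigengenes.loc[mname, common].to_numpy(float)
        for t in traits.columns:
            y = traits.loc[common, t].to_numpy(float)
            if np.std(y) == 0:
                raise ValueError(f"trait {t!r} is constant")
            rr, pp = stats.pearsonr(e, y)
            r.loc[mname, t] = rr
            p.loc[mname, t] = pp
    return r, p


def mm_gs_hubs(expr: pd.DataFrame, labels: pd.Series,
               eigengenes: pd.DataFrame, trait: pd.Series,
               mm_thr: float = 0.7, gs_thr: float = 0.2) -> ModuleSet:
    """Module membership, gene significance and hub calls.

    MM(g, M) = cor(x_g, eigengene_M); GS(g) = cor(x_g, trait); a gene is a
    hub of its own module iff |MM| > mm_thr and |GS| > gs_thr (strict).
    """
    common = [c for c in expr.columns if c in trait.index]
    x = expr[common].to_numpy(float)
    y = trait.loc[common].to_numpy(float)

    def _cor(a: np.ndarray, b: np.ndarray) -> float:
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    gs = pd.Series({g: _cor(x[i], y) for i, g in enumerate(expr.index)})
    mm = pd.DataFrame(index=expr.index, columns=eigengenes.index, dtype=float)
    for mname in eigengenes.index:
        e = eigengenes.loc[mname, common].to_numpy(float)
        mm[mname] = [_cor(x[i], e) for i in range(len(expr.index))]
    hubs: Dict[str, List[str]] = {}
    for mname in eigengenes.index:
        members = labels.index[labels == mname]
        hubs[mname] = [g for g in members
                       if abs(mm.loc[g, mname]) > mm_thr and abs(gs[g]) > gs_thr]
    return ModuleSet(labels=labels, eigengenes=eigengenes, mm=mm, gs=gs,
                     hubs=hubs)
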