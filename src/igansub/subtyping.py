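"""Unsupervised subtype discovery by a three-clusterer consensus vote.

Three algorithms partition the case samples on the expression of the
case-vs-control DEG set: Ward hierarchical clustering, PAM k-medoids, and
Monti-style consensus clustering (resampled hierarchical runs aggregated
into a co-clustering matrix).  Their label vectors are harmonized by a
Hungarian assignment against a reference and combined by a 2-of-3 majority
vote; samples with three-way disagreement stay unassigned.

The number of subtypes is chosen by majority among three criteria: the
Tibshirani gap statistic, the mean-silhouette maximizer over PAM labels,
and the consensus-CDF delta-area rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .simulate import UNASSIGNED

log = logging.getLogger(__name__)


def _sample_matrix(expr_subset: pd.DataFrame) -> np.ndarray:
    """samples x features view of a genes x samples frame."""
    return expr_subset.to_numpy(float).T


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (determinism)."""
    mapping: Dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def hierarchical_labels(expr_subset: pd.DataFrame, k: int,
                        method: str = "ward") -> np.ndarray:
    """Ward (Euclidean) hierarchical clustering of samples cut to k groups."""
    X = _sample_matrix(expr_subset)
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of samples")
    if k == 1:
        return np.ones(X.shape[0], dtype=int)
    Z = linkage(X, method=method)
    return _canonical(fcluster(Z, t=k, criterion="maxclust"))


def medoid_labels(expr_subset: pd.DataFrame, k: int, seed: int = 0,
                  max_iter: int = 100) -> np.ndarray:
    """PAM k-medoids (BUILD + SWAP to a local optimum) on Euclidean distance.

    The seed only breaks ties among equal-cost swaps; the procedure is
    otherwise deterministic.
    """
    X = _sample_matrix(expr_subset)
    n = X.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of samples")
    D = squareform(pdist(X))
    rng = np.random.default_rng(seed)

    # BUILD: greedy cost minimization
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dist_to_near = D[:, medoids].min(axis=1)
        gains = np.maximum(dist_to_near[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = np.flatnonzero(gains == gains.max())
        medoids.append(int(rng.choice(best)))

    def cost(meds: List[int]) -> float:
        return float(D[:, meds].min(axis=1).sum())

    current = cost(medoids)
    for _ in range(max_iter):  # SWAP
        best_delta, best_swaps = 0.0, []
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                delta = cost(trial) - current
                if delta < best_delta - 1e-12:
                    best_delta, best_swaps = delta, [(mi, h)]
                elif best_swaps and abs(delta - best_delta) <= 1e-12:
                    best_swaps.append((mi, h))
        if not best_swaps:
            break
        mi, h = best_swaps[int(rng.integers(len(best_swaps)))]
        medoids[mi] = h
        current = cost(medoids)
    assign = np.argmin(D[:, medoids], axis=1)
    return _canonical(assign + 1)


def consensus_cluster(expr_subset: pd.DataFrame, k: int,
                      n_resample: int = 100, sample_frac: float = 0.8,
                      seed: int = 0) -> Tuple[pd.DataFrame, np.ndarray]:
    """Monti-style consensus clustering of samples.

    Each resample draws ceil(frac*n) samples without replacement and runs
    Ward hierarchical clustering at k; consensus(i,j) = co-clustered count /
    co-sampled count.  Final labels come from average-linkage clustering of
    (1 - consensus) cut at k.
    """
    if n_resample < 2:
        raise ValueError("n_resample must be >= 2")
    X = _sample_matrix(expr_subset)
    n = X.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of samples")
    rng = np.random.default_rng(seed)
    m = math.ceil(sample_frac * n)
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(n_resample):
        idx = rng.choice(n, size=m, replace=False)
        sub = X[idx]
        if k == 1:
            labs = np.ones(m, dtype=int)
        else:
            labs = fcluster(linkage(sub, method="ward"), t=k,
                            criterion="maxclust")
        same = (labs[:, None] == labs[None, :]).astype(float)
        co_sample[np.ix_(idx, idx)] += 1.0
        co_cluster[np.ix_(idx, idx)] += same
    never = co_sample == 0
    if never.any():
        log.warning("consensus_cluster: %d sample pairs never co-sampled",
                    int(never.sum() // 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        cons = np.where(never, 0.0, co_cluster / np.where(never, 1.0, co_sample))
    np.fill_diagonal(cons, 1.0)
    cons = (cons + cons.T) / 2.0

    d = 1.0 - cons
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    labels = _canonical(fcluster(Z, t=k, criterion="maxclust"))
    cons_df = pd.DataFrame(cons, index=expr_subset.columns,
                           columns=expr_subset.columns)
    return cons_df, labels


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Sum over clusters of squared distances to the cluster centroid."""
    w = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def gap_statistic(expr_subset: pd.DataFrame, k_values: Sequence[int],
                  n_ref: int = 50, seed: int = 0) -> pd.DataFrame:
    """Tibshirani gap statistic on hierarchical labels.

    Reference datasets are uniform over each feature's observed range;
    returns a table with gap and the simulation-adjusted SE per k.
    """
    X = _sample_matrix(expr_subset)
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    refs = [rng.uniform(lo, hi, size=X.shape) for _ in range(n_ref)]
    rows = []
    for k in k_values:
        labs = hierarchical_labels(expr_subset, k)
        log_w = math.log(_within_dispersion(X, labs))
        ref_logs = []
        for R in refs:
            if k == 1:
                rl = np.ones(R.shape[0], dtype=int)
            else:
                rl = fcluster(linkage(R, method="ward"), t=k,
                              criterion="maxclust")
            ref_logs.append(math.log(_within_dispersion(R, rl)))
        ref_logs = np.asarray(ref_logs)
        gap = float(ref_logs.mean() - log_w)
        sk = float(ref_logs.std(ddof=0) * math.sqrt(1.0 + 1.0 / n_ref))
        rows.append((k, gap, sk))
    return pd.DataFrame(rows, columns=["k", "gap", "se"])


def _first_se_max(table: pd.DataFrame) -> int:
    """Smallest k with gap(k) >= gap(k+1) - se(k+1); falls back to argmax."""
    ks = table["k"].to_numpy()
    gap = table["gap"].to_numpy()
    se = table["se"].to_numpy()
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            return int(ks[i])
    return int(ks[np.argmax(gap)])


def consensus_cdf_area(consensus: pd.DataFrame) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    vals = consensus.to_numpy()
    iu = np.triu_indices_from(vals, k=1)
    x = np.sort(vals[iu])
    m = len(x)
    # integral over [0, 1] of the step CDF: F = i/m on [x_i, x_{i+1})
    breaks = np.concatenate([[0.0], x, [1.0]])
    heights = np.concatenate([[0.0], np.arange(1, m + 1) / m])
    return float(np.sum(np.diff(breaks) * heights))


@dataclass
class KSelection:
    """Per-method optimal k plus diagnostics."""

    gap_k: int
    silhouette_k: int
    cdf_k: int
    majority_k: int
    gap_table: pd.DataFrame
    silhouette_table: pd.DataFrame
    cdf_table: pd.DataFrame


def select_k(expr_subset: pd.DataFrame, k_range: Tuple[int, int] = (2, 10),
             seed: int = 0, n_ref: int = 50, n_resample: int = 100,
             sample_frac: float = 0.8, cdf_tol: float = 0.1) -> KSelection:
    """Choose the number of subtypes by three criteria and majority vote.

    * gap: Tibshirani gap statistic (uniform reference over feature ranges,
      firstSEmax rule) on hierarchical labels;
    * silhouette: mean-silhouette maximizer over PAM labels;
    * cdf: consensus-CDF delta-area rule — the k (> k_min) maximizing the
      relative increase in CDF area, or k_min when no increase exceeds
      ``cdf_tol``.

    Raises when the three criteria all disagree.
    """
    k_min, k_max = k_range
    n = expr_subset.shape[1]
    if not (2 <= k_min <= k_max <= n - 1):
        raise ValueError("k_range must lie within [2, n_samples - 1]")
    ks = list(range(k_min, k_max + 1))

    gap_tab = gap_statistic(expr_subset, ks, n_ref=n_ref, seed=seed)
    gap_k = _first_se_max(gap_tab)

    X = _sample_matrix(expr_subset)
    sil_rows = []
    for k in ks:
        labs = medoid_labels(expr_subset, k, seed=seed)
        if len(np.unique(labs)) < 2:
            sil_rows.append((k, -1.0))
            continue
        sil_rows.append((k, float(silhouette_score(X, labs))))
    sil_tab = pd.DataFrame(sil_rows, columns=["k", "silhouette"])
    silhouette_k = int(sil_tab.loc[sil_tab["silhouette"].idxmax(), "k"])

    areas = []
    for k in ks:
        cons, _ = consensus_cluster(expr_subset, k, n_resample=n_resample,
                                    sample_frac=sample_frac, seed=seed + k)
        areas.append(consensus_cdf_area(cons))
    deltas = [float("nan")]
    for i in range(1, len(ks)):
        deltas.append((areas[i] - areas[i - 1]) / areas[i - 1])
    cdf_tab = pd.DataFrame({"k": ks, "area": areas, "delta": deltas})
    if len(ks) == 1:
        cdf_k = ks[0]
    else:
        d = np.asarray(deltas[1:])
        cdf_k = ks[0] if np.nanmax(d) <= cdf_tol else ks[1 + int(np.nanargmax(d))]

    votes = [gap_k, silhouette_k, cdf_k]
    counts = {v: votes.count(v) for v in votes}
    best = max(counts.items(), key=lambda kv: kv[1])
    if best[1] < 2:
        raise ValueError("no majority k; fix k explicitly")
    return KSelection(gap_k, silhouette_k, cdf_k, best[0],
                      gap_tab, sil_tab, cdf_tab)


def harmonize_labels(label_vectors: Sequence[Sequence[int]],
                     reference_index: int = 0) -> List[np.ndarray]:
    """Align cluster label vectors to a reference by Hungarian assignment.

    Each non-reference vector is relabeled by the permutation of 1..k that
    maximizes agreement with the reference (maximum-weight matching on the
    k x k contingency table).  The reference is returned unchanged.
    """
    vectors = [np.asarray(v, dtype=int) for v in label_vectors]
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError("label vectors differ in length")
    ks = {len(np.unique(v)) for v in vectors}
    if len(ks) != 1:
        raise ValueError("label vectors have differing numbers of clusters")
    ref = vectors[reference_index]
    ref_levels = np.unique(ref)
    out: List[np.ndarray] = []
    for i, v in enumerate(vectors):
        if i == reference_index:
            out.append(v.copy())
            continue
        levels = np.unique(v)
        cont = np.zeros((len(levels), len(ref_levels)))
        for a, la in enumerate(levels):
            for b, lb in enumerate(ref_levels):
                cont[a, b] = np.sum((v == la) & (ref == lb))
        rows, cols = linear_sum_assignment(-cont)
        mapping = {levels[a]: ref_levels[b] for a, b in zip(rows, cols)}
        out.append(np.array([mapping[x] for x in v]))
    return out


def vote_consensus(aligned_vectors: Sequence[Sequence[int]],
                   sample_ids: Sequence[str]) -> pd.DataFrame:
    """2-of-3 majority vote over harmonized label vectors.

    A sample receives a final subtype whenever at least two of the three
    algorithms agree; three-way disagreement leaves it unassigned (0).
    """
    if len(aligned_vectors) != 3:
        raise ValueError("exactly 3 aligned label vectors required")
    hier, medoid, cons = (np.asarray(v, dtype=int) for v in aligned_vectors)
    final = np.full(len(hier), UNASSIGNED, dtype=int)
    for i, triple in enumerate(zip(hier, medoid, cons)):
        for lab in triple:
            if triple.count(lab) >= 2:
                final[i] = lab
                break
    n_un = int((final == UNASSIGNED).sum())
    if n_un:
        log.info("vote_consensus: %d/%d samples unassigned", n_un, len(final))
    return pd.DataFrame({
        "sample_id": list(sample_ids),
        "hier": hier, "medoid": medoid, "consensus": cons,
        "final": final,
    })


def discover_subtypes(expr_degs: pd.DataFrame, k: int, seed: int = 0,
                      n_resample: int = 100, sample_frac: float = 0.8,
                      ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run all three clusterers at k, harmonize against the consensus
    labels (the most stable of the three) and vote.  Returns the assignment
    table and the consensus matrix."""
    hier = hierarchical_labels(expr_degs, k)
    med = medoid_labels(expr_degs, k, seed=seed)
    cons_mat, cons = consensus_cluster(expr_degs, k, n_resample=n_resample,
                                       sample_frac=sample_frac, seed=seed)
    aligned = harmonize_labels([cons, hier, med], reference_index=0)
    assignment = vote_consensus([aligned[1], aligned[2], aligned[0]],
                                expr_degs.columns)
    return assignment, cons_mat
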