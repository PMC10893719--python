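"""Over-representation and pre-ranked enrichment of gene sets.

* ``ora_test``: upper-tail hypergeometric over-representation of a query
  gene list within a set, against an explicit universe.
* ``gsea_preranked``: weighted Kolmogorov-Smirnov running-sum enrichment
  score over a ranked gene list, with gene-label permutations for the
  normalized score and p-value.

Both operate on caller-supplied GMT collections; no term database is
bundled.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


def ora_test(query: Sequence[str], gene_set: Sequence[str],
             universe: Sequence[str]) -> Tuple[int, float, float]:
    """Hypergeometric over-representation test.

    Returns (overlap, p, fold_enrichment) where p = P(X >= overlap) for a
    hypergeometric draw of |query| genes from the universe containing
    |set ∩ universe| marked genes.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty universe")
    q = list(dict.fromkeys(query))
    if not q:
        raise ValueError("empty query")
    uni_set = set(uni)
    if not set(q) <= uni_set:
        raise ValueError("query must be a subset of the universe")
    marked = set(gene_set) & uni_set
    overlap = len(set(q) & marked)
    N, K, n = len(uni), len(marked), len(q)
    p = float(stats.hypergeom.sf(overlap - 1, N, K, n)) if K else 1.0
    fold = (overlap / n) / (K / N) if K else 0.0
    return overlap, p, float(fold)


def ora_collection(query: Sequence[str], gene_sets, universe: Sequence[str],
                   ) -> pd.DataFrame:
    """ORA over a name -> genes collection, BH-adjusted across sets."""
    from .differential import bh_adjust

    rows = []
    for name, genes in gene_sets.items():
        k, p, fold = ora_test(query, genes, universe)
        rows.append((name, k, fold, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "fold_enrichment", "p"])
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


def _running_es(hit: np.ndarray, weights: np.ndarray) -> Tuple[float, np.ndarray]:
    """Enrichment score of one hit indicator over the ranked list.

    ``weights`` are the per-position hit increments (|score|^w, not yet
    normalized); misses decrement by 1/(N - m).
    """
    n = hit.size
    m = int(hit.sum())
    hit_w = weights * hit
    denom = hit_w.sum()
    if denom <= 0:  # all weights zero: fall back to equal hit steps
        hit_w = hit.astype(float)
        denom = float(m)
    steps = hit_w / denom - (1.0 - hit) / (n - m)
    running = np.cumsum(steps)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def gsea_preranked(scores: pd.Series, gene_set: Sequence[str],
                   weight: float = 1.0, n_perm: int = 1000, seed: int = 0,
                   ) -> Tuple[float, float, float]:
    """Pre-ranked GSEA enrichment score with gene-label permutations.

    ``scores`` maps gene id -> ranking statistic; genes are walked in
    descending score order.  Hits are weighted by |score|^weight
    (normalized to sum 1), misses by -1/(N - m); ES is the extremum of the
    running sum.  The p-value and NES come from ``n_perm`` random
    placements of the m set genes among the N positions, matched on the
    sign of the observed ES.

    Returns (ES, NES, p).
    """
    scores = scores.sort_values(ascending=False, kind="mergesort")
    ranked_genes = np.asarray(scores.index)
    vals = scores.to_numpy(float)
    if not np.isfinite(vals).all():
        raise ValueError("scores must be finite")
    in_set = np.isin(ranked_genes, list(gene_set))
    m = int(in_set.sum())
    n = len(ranked_genes)
    if m == 0:
        raise ValueError("gene set has no genes in the ranking")
    if m == n:
        raise ValueError("gene set covers the whole ranking")
    weights = np.abs(vals) ** weight
    es, _ = _running_es(in_set.astype(float), weights)

    rng = np.random.default_rng(seed)
    # random hit placements: m smallest entries of a random row
    u = rng.random((n_perm, n))
    idx = np.argpartition(u, m - 1, axis=1)[:, :m]
    hits = np.zeros((n_perm, n))
    np.put_along_axis(hits, idx, 1.0, axis=1)
    hit_w = hits * weights[None, :]
    denom = hit_w.sum(axis=1, keepdims=True)
    denom = np.where(denom <= 0, 1.0, denom)
    steps = hit_w / denom - (1.0 - hits) / (n - m)
    running = np.cumsum(steps, axis=1)
    flat_idx = np.argmax(np.abs(running), axis=1)
    perm_es = running[np.arange(n_perm), flat_idx]

    same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
    pool = perm_es[same_sign]
    if pool.size == 0:
        return es, float("nan"), 1.0 / (n_perm + 1)
    p = (1.0 + float(np.sum(np.abs(pool) >= abs(es)))) / (pool.size + 1.0)
    nes = es / float(np.mean(np.abs(pool)))
    return es, float(nes), float(p)


def gsea_collection(scores: pd.Series, gene_sets, weight: float = 1.0,
                    n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Pre-ranked GSEA over a collection, BH-adjusted across sets."""
    from .differential import bh_adjust

    rows = []
    for i, (name, genes) in enumerate(gene_sets.items()):
        es, nes, p = gsea_preranked(scores, genes, weight=weight,
                                    n_perm=n_perm, seed=seed + i)
        rows.append((name, es, nes, p))
    out = pd.DataFrame(rows, columns=["set", "es", "nes", "p"])
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out
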