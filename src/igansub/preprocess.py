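"""Probe-to-gene collapsing, batch adjustment and per-gene standardization.

The batch step is an exact per-gene location-scale standardization within
each batch (each batch's values are centred and scaled, then the gene's
pooled mean and pooled SD are restored).  This is a deliberate, documented
simplification of empirical-Bayes batch correction: it removes additive and
multiplicative batch offsets exactly and is fully deterministic; it lacks
the shrinkage that matters for very small batches.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SD_FLOOR = 1e-8


def collapse_probes(probe_matrix: pd.DataFrame,
                    probe_to_gene: Mapping[str, Iterable[str]] | pd.DataFrame,
                    ) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples.

    Probes mapping to no gene or to more than one gene are dropped.  For
    multiple probes of one gene the per-sample median is taken.  Gene order
    follows first appearance among surviving probes.
    """
    if isinstance(probe_to_gene, pd.DataFrame):
        mapping: dict[str, list[str]] = {}
        for probe, gene in zip(probe_to_gene.iloc[:, 0], probe_to_gene.iloc[:, 1]):
            mapping.setdefault(str(probe), []).append(str(gene))
    else:
        mapping = {p: list(gs) for p, gs in probe_to_gene.items()}

    gene_probes: dict[str, list[str]] = {}
    for probe in probe_matrix.index:
        genes = mapping.get(probe, [])
        if len(genes) != 1:  # unannotated or ambiguous probes are removed
            continue
        gene_probes.setdefault(genes[0], []).append(probe)
    if not gene_probes:
        raise ValueError("no annotatable probes")

    rows = {gene: probe_matrix.loc[probes].median(axis=0)
            for gene, probes in gene_probes.items()}
    out = pd.DataFrame(rows).T
    out.index.name = "gene_id"
    out.columns = probe_matrix.columns
    return out


def adjust_batches(expr: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Remove per-gene batch location/scale differences.

    Per gene and batch: subtract the batch mean, divide by the batch SD
    (floored at 1e-8), then restore the gene's pooled mean and pooled SD.
    Single-batch input is returned unchanged.  Preserves each gene's pooled
    mean exactly.
    """
    ann = annotation.set_index("sample_id").loc[list(expr.columns)]
    batches = ann["batch"].to_numpy()
    uniq = pd.unique(batches)
    if len(uniq) < 2:
        return expr.copy()
    for b in uniq:
        if (batches == b).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")

    x = expr.to_numpy(float)
    pooled_mean = x.mean(axis=1, keepdims=True)
    pooled_sd = x.std(axis=1, ddof=1, keepdims=True)
    z = np.empty_like(x)
    floored = 0
    for b in uniq:
        cols = batches == b
        m = x[:, cols].mean(axis=1, keepdims=True)
        sd = x[:, cols].std(axis=1, ddof=1, keepdims=True)
        low = sd < SD_FLOOR
        floored += int(low.sum())
        sd = np.where(low, SD_FLOOR, sd)
        z[:, cols] = (x[:, cols] - m) / sd
    if floored:
        log.warning("adjust_batches: floored %d zero-variance gene/batch SDs",
                    floored)
    out = z * np.where(pooled_sd < SD_FLOOR, SD_FLOOR, pooled_sd) + pooled_mean
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def zscore_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene row to mean 0, sample SD (n-1) 1.

    Constant rows are floored to SD 1e-8 (yielding ~0 rows) with a warning
    rather than dropped, keeping matrix shapes stable across stages.
    """
    x = expr.to_numpy(float)
    m = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    low = sd < SD_FLOOR
    if low.any():
        log.warning("zscore_genes: %d constant gene rows floored", int(low.sum()))
    sd = np.where(low, SD_FLOOR, sd)
    return pd.DataFrame((x - m) / sd, index=expr.index, columns=expr.columns)
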