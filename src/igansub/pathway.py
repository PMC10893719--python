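"""Expression-bias pathway activity scores and cross-subtype ANOVA.

For a gene g in a pathway, the normalized deviation is
``z_g = (mean_case(g) - mean_ctrl(g)) / sd_ctrl(g)``; the pathway's
activity score in a patient group is the mean of |z_g| over the pathway's
genes present in the matrix.  A higher score means the pathway's genes are
more dysregulated relative to the healthy baseline.

Significance across subtypes uses one-way ANOVA with the per-gene |z|
values as the replicates within each pathway x subtype cell (a single
aggregated score per subtype admits no ANOVA; the per-gene level is the
replicated reading of the procedure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

SD_FLOOR = 1e-8


@dataclass
class ActivityScore:
    pathway_id: str
    score: float
    n_genes_used: int
    abs_z: pd.Series  # per-gene |z| values, index = gene ids


def activity_score(expr: pd.DataFrame, case_ids: Sequence[str],
                   control_ids: Sequence[str], gene_set: Sequence[str],
                   pathway_id: str = "") -> ActivityScore:
    """Mean absolute control-SD-normalized case-control difference over a
    gene set.  Genes absent from the matrix are skipped (and not counted in
    n_genes_used); an empty intersection is an error."""
    if len(control_ids) < 2:
        raise ValueError("need at least 2 controls")
    genes = [g for g in dict.fromkeys(gene_set) if g in expr.index]
    if not genes:
        raise ValueError(f"gene set {pathway_id!r} has no genes in the matrix")
    case = expr.loc[genes, list(case_ids)].to_numpy(float)
    ctrl = expr.loc[genes, list(control_ids)].to_numpy(float)
    sd = ctrl.std(axis=1, ddof=1)
    low = sd < SD_FLOOR
    if low.any():
        log.warning("activity_score[%s]: %d control SDs floored",
                    pathway_id, int(low.sum()))
    sd = np.where(low, SD_FLOOR, sd)
    z = (case.mean(axis=1) - ctrl.mean(axis=1)) / sd
    abs_z = pd.Series(np.abs(z), index=genes)
    return ActivityScore(pathway_id=pathway_id, score=float(abs_z.mean()),
                         n_genes_used=len(genes), abs_z=abs_z)


def score_anova(groups: Mapping[object, Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA over per-gene |z| values grouped by subtype."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = []
    for key, vals in groups.items():
        v = np.asarray(list(vals), dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {key!r} has fewer than 2 values")
        arrays.append(v)
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    if np.isnan(f):  # zero within- and between-group variance
        return 0.0, 1.0
    return float(f), float(p)


def subtype_pathway_table(expr: pd.DataFrame, annotation: pd.DataFrame,
                          subtype_labels: pd.Series,
                          gene_sets: Mapping[str, Sequence[str]],
                          ) -> pd.DataFrame:
    """Tidy activity table: one row per pathway x subtype with the score,
    plus the pathway-level ANOVA across subtypes."""
    ctrl = annotation.loc[annotation["group"] == "control", "sample_id"].tolist()
    rows = []
    for name, genes in gene_sets.items():
        per_subtype: Dict[int, ActivityScore] = {}
        for s in sorted(set(subtype_labels) - {0}):
            cases = subtype_labels.index[subtype_labels == s].tolist()
            per_subtype[s] = activity_score(expr, cases, ctrl, genes, name)
        f, p = score_anova({s: a.abs_z.to_numpy() for s, a in per_subtype.items()})
        for s, a in per_subtype.items():
            rows.append((name, s, a.score, a.n_genes_used, f, p))
    return pd.DataFrame(rows, columns=["pathway", "subtype", "score",
                                       "n_genes", "F", "p"])
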