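"""Synthetic microarray cohorts with planted subtype structure.

The generator emulates the statistical shape of a merged two-batch IgA
nephropathy microarray cohort (107 cases, 14 healthy controls on the log2
intensity scale) with k planted molecular subtypes.  Every downstream stage
of the pipeline — differential screening, consensus subtyping, classifier
training, pathway scoring, co-expression modules, deconvolution, clinical
traits — can be exercised against the returned ground truth.

Design of the planted signal
----------------------------
* Baseline gene means are drawn N(7, 1.5^2) on the log2 scale (typical
  microarray intensity range); measurement noise is Gaussian.
* A *global* DE block is shifted in every case sample (13% up / 87% down,
  mimicking the strong down-regulation bias seen in real case-control
  screens of this disease).
* Each subtype owns a disjoint DE block.  Genes in a subtype block are
  shifted by ``effect_size`` in that subtype's cases *and* by a case-wide
  baseline component of ``0.5 * effect_size`` in all cases.  The case-wide
  component makes subtype genes visible to the global case-vs-control
  screen, so that the intersection rule "global DEGs ∩ subtype-vs-rest
  DEGs" — the definition of subtype-specific genes — has support, exactly
  as in real cohorts where subtype markers are also disease markers.  Both
  components scale with ``effect_size``, so ``effect_size=0`` is an exact
  null.
* Batches split cases and controls contiguously (each batch spans both
  groups, so batch is not confounded with disease status); batch offsets
  are drawn per gene per batch.
* Subtype sample counts follow largest-remainder rounding of
  ``subtype_props`` so allocation is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

UNASSIGNED = 0

#: fraction of global-DE genes shifted upward in cases
_GLOBAL_UP_FRACTION = 0.13
#: case-wide component of a subtype block shift, as a fraction of effect_size
_BASELINE_COMPONENT = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated case/control cohort.

    Defaults emulate the merged discovery cohort this pipeline was designed
    around: 107 cases, 14 controls, three subtypes of equal prevalence, two
    batches, log2-scale Gaussian noise of SD 1 and planted effects of 3
    log2 units.
    """

    n_case: int = 107
    n_ctrl: int = 14
    n_genes: int = 2000
    k_subtypes: int = 3
    subtype_props: Tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    n_de_per_subtype: int = 50
    n_global_de: int = 60
    effect_size: float = 3.0
    noise_sd: float = 1.0
    n_batches: int = 2
    batch_shift_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_ctrl", "n_genes", "k_subtypes",
                     "n_de_per_subtype", "n_batches"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_global_de < 0:
            raise ValueError("n_global_de must be nonnegative")
        if len(self.subtype_props) != self.k_subtypes:
            raise ValueError("subtype_props length must equal k_subtypes")
        if abs(sum(self.subtype_props) - 1.0) > 1e-9:
            raise ValueError("subtype_props must sum to 1")
        if any(p < 0 for p in self.subtype_props):
            raise ValueError("subtype_props must be nonnegative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0 or self.batch_shift_sd < 0:
            raise ValueError("noise/batch SDs must be >= 0")
        if self.n_global_de + self.k_subtypes * self.n_de_per_subtype > self.n_genes:
            raise ValueError("DE blocks exceed gene count")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    true_subtype: pd.Series  # per-case subtype label, 1..k
    true_de_genes: Dict[int, List[str]]  # subtype -> disjoint DE gene blocks
    true_global_de: List[str]
    gene_ids: List[str] = field(default_factory=list)
    pathway_sets: Dict[str, List[str]] = field(default_factory=dict)
    true_fractions: pd.DataFrame | None = None
    trait_loadings: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def all_case_shifted_genes(self) -> List[str]:
        """Genes whose case-wide mean differs from controls by construction
        (global block plus every subtype block, which carries a case-wide
        baseline component)."""
        out = list(self.true_global_de)
        for genes in self.true_de_genes.values():
            out.extend(genes)
        return out


def allocate_subtypes(n_case: int, props: Sequence[float]) -> List[int]:
    """Largest-remainder allocation of n_case samples to len(props) subtypes.

    Deterministic: quotas n*p are floored, leftover seats go to the largest
    fractional remainders (ties broken by lower subtype index).  Returns the
    per-subtype counts.
    """
    quotas = [n_case * p for p in props]
    counts = [math.floor(q) for q in quotas]
    short = n_case - sum(counts)
    order = sorted(range(len(props)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def _batch_assignment(n_case: int, n_ctrl: int, n_batches: int) -> np.ndarray:
    """Contiguous split of cases and of controls into n_batches chunks, so
    every batch spans both groups (batch is not confounded with status)."""

    def chunks(n: int) -> List[int]:
        base, extra = divmod(n, n_batches)
        out: List[int] = []
        for b in range(n_batches):
            out.extend([b] * (base + (1 if b < extra else 0)))
        return out

    return np.array(chunks(n_case) + chunks(n_ctrl), dtype=int)


def generate_cohort(config: SimConfig) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a genes x samples log2 expression matrix with annotation and
    ground truth.  Same config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_ctrl
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    case_ids = [f"IGAN_{i:03d}" for i in range(config.n_case)]
    ctrl_ids = [f"CTRL_{i:03d}" for i in range(config.n_ctrl)]
    sample_ids = case_ids + ctrl_ids
    is_case = np.array([True] * config.n_case + [False] * config.n_ctrl)

    counts = allocate_subtypes(config.n_case, config.subtype_props)
    # round-robin interleaving keeps every contiguous batch chunk spanning
    # all subtypes, so batch is confounded with neither status nor subtype
    remaining = list(counts)
    subtype_list: List[int] = []
    while len(subtype_list) < config.n_case:
        for s in range(config.k_subtypes):
            if remaining[s] > 0:
                subtype_list.append(s + 1)
                remaining[s] -= 1
    subtype_of_case = np.array(subtype_list, dtype=int)

    # disjoint DE blocks: global first, then one block per subtype
    cursor = 0
    global_idx = np.arange(cursor, cursor + config.n_global_de)
    cursor += config.n_global_de
    subtype_idx: Dict[int, np.ndarray] = {}
    for s in range(1, config.k_subtypes + 1):
        subtype_idx[s] = np.arange(cursor, cursor + config.n_de_per_subtype)
        cursor += config.n_de_per_subtype

    base_mean = rng.normal(7.0, 1.5, size=config.n_genes)
    values = base_mean[:, None] + rng.normal(0.0, config.noise_sd,
                                             size=(config.n_genes, n))

    # global block: shift every case, mostly downward
    n_up = int(round(_GLOBAL_UP_FRACTION * config.n_global_de))
    global_sign = np.where(np.arange(config.n_global_de) < n_up, 1.0, -1.0)
    rng.shuffle(global_sign)
    values[np.ix_(global_idx, np.where(is_case)[0])] += (
        config.effect_size * global_sign[:, None])

    # subtype blocks: case-wide baseline component + full effect in the
    # owning subtype's cases
    subtype_sign: Dict[int, np.ndarray] = {}
    case_cols = np.where(is_case)[0]
    for s in range(1, config.k_subtypes + 1):
        sign = rng.choice([-1.0, 1.0], size=config.n_de_per_subtype)
        subtype_sign[s] = sign
        values[np.ix_(subtype_idx[s], case_cols)] += (
            _BASELINE_COMPONENT * config.effect_size * sign[:, None])
        own_cols = case_cols[subtype_of_case == s]
        values[np.ix_(subtype_idx[s], own_cols)] += (
            config.effect_size * sign[:, None])

    batch = _batch_assignment(config.n_case, config.n_ctrl, config.n_batches)
    batch_offsets = rng.normal(0.0, config.batch_shift_sd,
                               size=(config.n_genes, config.n_batches))
    values += batch_offsets[:, batch]

    expr = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    ann = pd.DataFrame({
        "sample_id": sample_ids,
        "group": ["case"] * config.n_case + ["control"] * config.n_ctrl,
        "batch": batch,
        "subtype_true": list(subtype_of_case) + [UNASSIGNED] * config.n_ctrl,
    })

    true_de = {s: [gene_ids[i] for i in subtype_idx[s]]
               for s in range(1, config.k_subtypes + 1)}
    truth = GroundTruth(
        true_subtype=pd.Series(subtype_of_case, index=case_ids, name="subtype"),
        true_de_genes=true_de,
        true_global_de=[gene_ids[i] for i in global_idx],
        gene_ids=list(gene_ids),
        pathway_sets={f"signal_subtype{s}": list(g) for s, g in true_de.items()},
    )

    # clinical-trait loadings: an eGFR-like trait driven (negatively) by the
    # first subtype's block, a proteinuria-like trait driven by the last's;
    # coefficients follow each gene's planted shift direction so the loaded
    # genes' contributions reinforce rather than cancel
    truth.trait_loadings = {
        "eGFR_like": {true_de[1][i]: -0.5 * subtype_sign[1][i]
                      for i in range(min(3, config.n_de_per_subtype))},
        "proteinuria_like": {true_de[config.k_subtypes][i]:
                             0.5 * subtype_sign[config.k_subtypes][i]
                             for i in range(min(3, config.n_de_per_subtype))},
    }
    return expr, ann, truth


def generate_gene_sets(truth: GroundTruth, n_null_sets: int, set_size: int,
                       seed: int) -> Dict[str, List[str]]:
    """Gene-set collection for pathway/enrichment stages: one signal set per
    subtype (all of that subtype's planted DE genes, padded with random
    non-DE genes up to ``set_size``) plus ``n_null_sets`` sets drawn
    uniformly from non-DE genes."""
    rng = np.random.default_rng(seed)
    de_all = set(truth.all_case_shifted_genes())
    non_de = [g for g in truth.gene_ids if g not in de_all]

    max_pad = max((set_size - len(g) for g in truth.true_de_genes.values()),
                  default=0)
    if set_size > len(non_de) or max_pad > len(non_de):
        raise ValueError("not enough non-DE genes for null sets")
    sets: Dict[str, List[str]] = {}
    pad_pool = list(non_de)
    for s, genes in truth.true_de_genes.items():
        members = list(genes)
        if set_size > len(members):
            extra = rng.choice(len(pad_pool), size=set_size - len(members),
                               replace=False)
            members += [pad_pool[i] for i in sorted(extra)]
        sets[f"signal_subtype{s}"] = members

    if set_size > len(non_de):
        raise ValueError("not enough non-DE genes for null sets")
    for j in range(n_null_sets):
        pick = rng.choice(len(non_de), size=set_size, replace=False)
        sets[f"null_{j:02d}"] = [non_de[i] for i in sorted(pick)]
    return sets


def generate_signature(n_genes: int = 200,
                       cell_types: Sequence[str] = ("B", "CD4T", "CD8T", "NK", "Mono"),
                       markers_per_type: int = 20,
                       seed: int = 0) -> pd.DataFrame:
    """Nonnegative reference profile matrix (genes x cell types) with a
    block of strongly enriched marker genes per cell type, loosely shaped
    like an immune signature matrix on the linear intensity scale."""
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    if k < 2:
        raise ValueError("need at least 2 cell types")
    if markers_per_type * k > n_genes:
        raise ValueError("marker blocks exceed gene count")
    values = rng.lognormal(mean=1.0, sigma=0.5, size=(n_genes, k))
    for j in range(k):
        rows = slice(j * markers_per_type, (j + 1) * markers_per_type)
        values[rows, j] *= 8.0
    genes = [f"SIG{i:04d}" for i in range(n_genes)]
    return pd.DataFrame(values, index=genes, columns=list(cell_types))


def generate_mixtures(n_samples: int, signature: pd.DataFrame,
                      noise_sd: float, seed: int,
                      ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk mixtures of the signature's cell types.

    Fractions are drawn from a flat Dirichlet; each bulk column is
    signature @ fractions + Gaussian noise, clipped at zero.  Returns the
    bulk matrix and the true fractions (samples x cell types).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if signature.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    if (signature.values < 0).any():
        raise ValueError("signature must be nonnegative")
    rng = np.random.default_rng(seed)
    k = signature.shape[1]
    fractions = rng.dirichlet(np.ones(k), size=n_samples)
    bulk = signature.values @ fractions.T
    if noise_sd > 0:
        bulk = bulk + rng.normal(0.0, noise_sd, size=bulk.shape)
    bulk = np.clip(bulk, 0.0, None)
    sample_ids = [f"MIX_{i:03d}" for i in range(n_samples)]
    bulk_df = pd.DataFrame(bulk, index=signature.index, columns=sample_ids)
    frac_df = pd.DataFrame(fractions, index=sample_ids,
                           columns=list(signature.columns))
    return bulk_df, frac_df


def generate_modular_expression(module_sizes: Sequence[int] = (150, 150, 150),
                                n_background: int = 150,
                                n_samples: int = 80,
                                min_cor: float = 0.3, max_cor: float = 0.95,
                                seed: int = 0,
                                ) -> Tuple[pd.DataFrame, pd.Series]:
    """Expression with hub-structured co-expression modules.

    Each module is driven by one latent factor; gene memberships decay
    linearly from ``max_cor`` (hub) to ``min_cor`` (periphery), giving the
    heavy-tailed connectivity distribution a weighted co-expression network
    expects.  Background genes are pure noise.  Returns the matrix and the
    true gene -> module index (-1 = background).
    """
    rng = np.random.default_rng(seed)
    rows, truth_labels = [], []
    for m, size in enumerate(module_sizes):
        factor = rng.normal(size=n_samples)
        for c in np.linspace(max_cor, min_cor, size):
            rows.append(c * factor
                        + math.sqrt(1 - c * c) * rng.normal(size=n_samples))
            truth_labels.append(m)
    for _ in range(n_background):
        rows.append(rng.normal(size=n_samples))
        truth_labels.append(-1)
    genes = [f"G{i:05d}" for i in range(len(rows))]
    expr = pd.DataFrame(np.asarray(rows), index=genes,
                        columns=[f"S{j:03d}" for j in range(n_samples)])
    return expr, pd.Series(truth_labels, index=genes, name="module")


def generate_traits(expr: pd.DataFrame, truth: GroundTruth,
                    annotation: pd.DataFrame, noise_sd: float,
                    seed: int) -> pd.DataFrame:
    """Clinical-trait table (cases only): each trait is a linear combination
    of its loaded genes' expression plus Gaussian noise.  Stands in for
    renal traits such as eGFR and proteinuria."""
    if not truth.trait_loadings:
        raise ValueError("trait_loadings is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    case_ids = annotation.loc[annotation["group"] == "case", "sample_id"].tolist()
    out = {}
    for trait, loadings in truth.trait_loadings.items():
        vals = np.zeros(len(case_ids))
        for gene, coef in loadings.items():
            if gene not in expr.index:
                raise KeyError(f"loaded gene {gene!r} absent from matrix")
            vals = vals + coef * expr.loc[gene, case_ids].to_numpy(float)
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=len(case_ids))
        out[trait] = vals
    return pd.DataFrame(out, index=pd.Index(case_ids, name="sample_id"))
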