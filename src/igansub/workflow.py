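"""End-to-end pipeline orchestration.

``run_pipeline`` chains the stages — simulate, batch adjustment, global
DEG screen, consensus subtyping, single-sample classifier, subtype DEGs
and subtype-specific genes, clinical-trait correlation, pathway activity,
co-expression modules, deconvolution and enrichment — writing every stage
output as TSV plus a JSON manifest of parameters, seeds and file hashes.
A fixed global seed makes the whole run reproducible; per-stage seeds are
derived from it by hashing the stage name, so single stages rerun
identically in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .classifier import cross_validate, evaluate, split_train_test, tune_forest
from .coexpression import (compute_eigengenes, detect_modules, merge_modules,
                           mm_gs_hubs, module_trait_correlation,
                           pick_soft_threshold, adjacency_matrix,
                           tom_transform, variance_filter, GREY)
from .deconvolution import (compare_fractions, estimate_fractions,
                            fraction_correlations)
from .differential import (DEGThresholds, SUBTYPE_THRESHOLDS,
                           gene_trait_correlation, subtype_specific_genes,
                           subtype_vs_rest_degs, two_group_degs)
from .enrichment import gsea_collection, ora_collection
from .pathway import subtype_pathway_table
from .preprocess import adjust_batches, zscore_genes
from .simulate import (SimConfig, UNASSIGNED, generate_cohort,
                       generate_gene_sets, generate_mixtures,
                       generate_signature, generate_traits)
from .subtyping import discover_subtypes, select_k

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the global one."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """All pipeline parameters, defaulting to the protocol's canonical
    values: global DEG cutoffs (0.05, 1.7); per-subtype cutoffs (0.01, 2),
    (0.01, 1.5), (0.01, 1.2); 3:1 split; 5 folds; top 25% variance filter;
    scale-free R^2 target 0.9; min module size 30; merge cut 0.25; hub
    thresholds |MM| > 0.7, |GS| > 0.2."""

    sim: SimConfig = field(default_factory=SimConfig)
    k_subtypes: int | str = "auto"
    global_alpha: float = 0.05
    global_lfc: float = 1.7
    split_ratio: float = 0.75
    cv_folds: int = 5
    top_frac: float = 0.25
    r2_target: float = 0.9
    min_module_size: int = 30
    merge_cut: float = 0.25
    mm_thr: float = 0.7
    gs_thr: float = 0.2
    n_resample: int = 100
    sample_frac: float = 0.8
    mtry_grid: tuple | None = None  # None = default_grids(p)
    ntree_grid: tuple | None = None
    seed: int = 0
    run_subtyping: bool = True
    run_classifier: bool = True
    run_pathways: bool = True
    run_coexpression: bool = True
    run_deconvolution: bool = True
    run_enrichment: bool = True

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | os.PathLike) -> Dict:
    """Execute the configured stages in dependency order.

    Writes stage TSVs under ``outdir`` plus ``manifest.json`` recording the
    full parameter block, derived seeds and output hashes.  Returns a dict
    of in-memory results keyed by stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.run_classifier and not config.run_subtyping:
        raise ValueError("classifier requires subtype labels")
    results: Dict = {}
    written: Dict[str, str] = {}

    def save(df: pd.DataFrame, name: str, index: bool = True,
             index_label: str | None = None) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index, index_label=index_label)
        written[name] = _sha256(path)

    # --- simulate -------------------------------------------------------
    expr_raw, ann, truth = generate_cohort(config.sim)
    save(expr_raw, "expression_raw.tsv", index_label="gene_id")
    save(ann, "annotation.tsv", index=False)
    results["truth"] = truth

    # --- preprocess -----------------------------------------------------
    expr = adjust_batches(expr_raw, ann)
    expr_z = zscore_genes(expr)
    save(expr, "expression_adjusted.tsv", index_label="gene_id")
    results["expr"] = expr

    case_ids = ann.loc[ann["group"] == "case", "sample_id"].tolist()
    ctrl_ids = ann.loc[ann["group"] == "control", "sample_id"].tolist()

    # --- global DEG screen (log2FC on the unscaled adjusted matrix) -----
    thr = DEGThresholds(config.global_alpha, config.global_lfc)
    global_degs = two_group_degs(expr, ann["group"].tolist(), thr,
                                 group1="case", group2="control")
    save(global_degs, "global_degs.tsv", index=False)
    results["global_degs"] = global_degs
    deg_genes = global_degs["gene_id"].tolist()
    if not deg_genes:
        raise RuntimeError("global DEG screen returned no genes")

    # --- subtype discovery on the z-scored DEG submatrix (cases only) ---
    labels = None
    if config.run_subtyping:
        sseed = stage_seed(config.seed, "subtyping")
        feat = expr_z.loc[deg_genes, case_ids]
        if config.k_subtypes == "auto":
            sel = select_k(feat, k_range=(2, 6), seed=sseed,
                           n_resample=config.n_resample,
                           sample_frac=config.sample_frac)
            k = sel.majority_k
            results["k_selection"] = sel
        else:
            k = int(config.k_subtypes)
        assignment, cons = discover_subtypes(
            feat, k, seed=sseed, n_resample=config.n_resample,
            sample_frac=config.sample_frac)
        save(assignment, "subtype_labels.tsv", index=False)
        save(cons, "consensus_matrix.tsv", index_label="sample_id")
        results["assignment"] = assignment
        results["consensus"] = cons
        results["k"] = k
        labels = pd.Series(assignment["final"].to_numpy(),
                           index=assignment["sample_id"])

    # --- classifier -----------------------------------------------------
    if config.run_classifier:
        cseed = stage_seed(config.seed, "classifier")
        assigned = labels.index[labels != UNASSIGNED].tolist()
        y = labels.loc[assigned]
        train, test = split_train_test(assigned, y.to_numpy(),
                                       ratio=config.split_ratio, seed=cseed)
        model = tune_forest(expr_z.loc[deg_genes, train],
                            y.loc[train].to_numpy(), seed=cseed,
                            mtry_grid=config.mtry_grid,
                            ntree_grid=config.ntree_grid)
        report = evaluate(model, expr_z.loc[deg_genes, test],
                          y.loc[test].to_numpy())
        report.cv_accuracy = cross_validate(expr_z.loc[deg_genes, assigned],
                                            y.to_numpy(),
                                            folds=config.cv_folds, seed=cseed,
                                            mtry_grid=config.mtry_grid,
                                            ntree_grid=config.ntree_grid)
        results["classifier_model"] = model
        results["classifier_report"] = report
        rep_df = pd.DataFrame([{
            "accuracy": report.accuracy, "macro_auc": report.macro_auc,
            "oob_error": report.oob_error, "cv_accuracy": report.cv_accuracy,
            "mtry": report.chosen_mtry, "ntree": report.chosen_ntree,
            **{f"auc_{c}": v for c, v in report.per_class_auc.items()},
        }])
        save(rep_df, "classifier_report.tsv", index=False)

    # --- subtype-vs-rest DEGs and subtype-specific genes ----------------
    specific: Dict[int, pd.DataFrame] = {}
    if config.run_subtyping:
        case_expr = expr[case_ids]
        sub_labels = labels.loc[case_ids]
        for s in sorted(set(sub_labels) - {UNASSIGNED}):
            sthr = SUBTYPE_THRESHOLDS.get(s, DEGThresholds(0.01, 1.2))
            degs_s = subtype_vs_rest_degs(case_expr, sub_labels.to_numpy(),
                                          s, sthr)
            spec = subtype_specific_genes(global_degs, degs_s)
            specific[s] = spec
            save(degs_s, f"subtype{s}_degs.tsv", index=False)
            save(spec, f"subtype{s}_specific_genes.tsv", index=False)
        results["subtype_specific"] = specific

        # clinical traits and gene-trait correlation
        tseed = stage_seed(config.seed, "traits")
        traits = generate_traits(expr, truth, ann, noise_sd=1.0, seed=tseed)
        save(traits, "traits.tsv", index_label="sample_id")
        corr_tables = {}
        for trait_name in traits.columns:
            genes = sorted({g for df in specific.values()
                            for g in df["gene_id"]})
            if genes:
                corr_tables[trait_name] = gene_trait_correlation(
                    expr[case_ids], traits[trait_name], genes)
                save(corr_tables[trait_name],
                     f"gene_trait_{trait_name}.tsv", index=False)
        results["trait_correlations"] = corr_tables

    # --- pathway activity ----------------------------------------------
    if config.run_pathways and config.run_subtyping:
        gseed = stage_seed(config.seed, "gene_sets")
        sets = generate_gene_sets(truth, n_null_sets=5, set_size=50,
                                  seed=gseed)
        gio.write_gmt(sets, out / "gene_sets.gmt")
        written["gene_sets.gmt"] = _sha256(out / "gene_sets.gmt")
        act = subtype_pathway_table(expr, ann, labels.loc[case_ids], sets)
        save(act, "pathway_activity.tsv", index=False)
        results["pathway_activity"] = act
        results["gene_sets"] = sets

    # --- enrichment -----------------------------------------------------
    if config.run_enrichment and config.run_subtyping and config.run_pathways:
        eseed = stage_seed(config.seed, "enrichment")
        universe = list(expr.index)
        ora_frames = []
        for s, spec in specific.items():
            if spec.empty:
                continue
            tab = ora_collection(spec["gene_id"].tolist(),
                                 results["gene_sets"], universe)
            tab.insert(0, "subtype", s)
            ora_frames.append(tab)
        if ora_frames:
            ora_all = pd.concat(ora_frames, ignore_index=True)
            save(ora_all, "ora_subtype_specific.tsv", index=False)
            results["ora"] = ora_all
        # pre-ranked GSEA on subtype-1 vs rest log2FC
        case_expr = expr[case_ids]
        sub_labels = labels.loc[case_ids].to_numpy()
        full = two_group_degs(case_expr,
                              np.where(sub_labels == 1, "target", "rest"),
                              DEGThresholds(1.0, 0.0), group1="target",
                              group2="rest")
        ranks = full.set_index("gene_id")["log2fc"]
        gsea = gsea_collection(ranks, results["gene_sets"], n_perm=500,
                               seed=eseed)
        save(gsea, "gsea_subtype1.tsv", index=False)
        results["gsea"] = gsea

    # --- co-expression network -----------------------------------------
    if config.run_coexpression and config.run_subtyping:
        # unscaled adjusted matrix: the variance filter needs real per-gene
        # variances, and correlations are scale-invariant downstream
        filt = variance_filter(expr[case_ids], config.top_frac)
        beta, fit_tab = pick_soft_threshold(filt, r2_target=config.r2_target)
        adj = adjacency_matrix(filt, beta)
        tom = tom_transform(adj.to_numpy())
        modules = detect_modules(tom, filt.index,
                                 min_module_size=config.min_module_size)
        merged_labels, eig = merge_modules(filt, modules.labels,
                                           cut_height=config.merge_cut)
        indicators = pd.DataFrame(
            {f"subtype_{s}": (labels.loc[case_ids] == s).astype(float)
             for s in sorted(set(labels.loc[case_ids]) - {UNASSIGNED})},
            index=case_ids)
        r_mt, p_mt = module_trait_correlation(eig, indicators)
        hub_trait = indicators.iloc[:, 0]
        mods = mm_gs_hubs(filt, merged_labels, eig, hub_trait,
                          mm_thr=config.mm_thr, gs_thr=config.gs_thr)
        save(pd.DataFrame({"gene_id": merged_labels.index,
                           "module": merged_labels.to_numpy()}),
             "modules.tsv", index=False)
        save(eig, "eigengenes.tsv", index_label="module")
        save(r_mt, "module_trait_r.tsv", index_label="module")
        save(p_mt, "module_trait_p.tsv", index_label="module")
        save(fit_tab, "soft_threshold_fit.tsv", index=False)
        hub_rows = [(mname, g) for mname, gs_ in mods.hubs.items() for g in gs_]
        save(pd.DataFrame(hub_rows, columns=["module", "gene_id"]),
             "hub_genes.tsv", index=False)
        results["beta"] = beta
        results["modules"] = mods
        results["merged_labels"] = merged_labels
        results["module_trait_r"] = r_mt

    # --- deconvolution (separate mixture experiment) --------------------
    if config.run_deconvolution:
        dseed = stage_seed(config.seed, "deconvolution")
        signature = generate_signature(seed=dseed)
        bulk, true_frac = generate_mixtures(60, signature, noise_sd=0.1,
                                            seed=dseed)
        est = estimate_fractions(bulk, signature)
        groups = ["A" if i < 30 else "B" for i in range(60)]
        tests = compare_fractions(est, groups, control="B")
        r_cc, p_cc = fraction_correlations(est)
        save(signature, "signature.tsv", index_label="gene_id")
        save(est, "cell_fractions.tsv", index_label="sample_id")
        save(true_frac, "cell_fractions_true.tsv", index_label="sample_id")
        save(tests, "fraction_tests.tsv", index=False)
        save(r_cc, "fraction_correlations.tsv", index_label="cell_type")
        results["fractions"] = est
        results["true_fractions"] = true_frac

    manifest = {
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s)
                        for s in ("subtyping", "classifier", "traits",
                                  "gene_sets", "enrichment", "deconvolution")},
        "outputs": written,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
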