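import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import igansub as ig


def _bh_brute(p):
    """Independent step-up BH: adj_i = min_{j: p_j >= p_i} p_j * n / rank_j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(n)
    for i in range(n):
        cands = [p[order[j]] * n / (j + 1) for j in range(i, n)]
        adj_sorted[i] = min(1.0, min(cands))
    out = np.empty(n)
    out[order] = adj_sorted
    return out


class TestBHAdjust:
    def test_hand_example(self):
        assert np.allclose(ig.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_values(self):
        assert ig.bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(ig.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ig.bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 40))
    def test_matches_brute_force_and_statsmodels(self, seed, n):
        p = np.random.default_rng(seed).uniform(size=n)
        ours = ig.bh_adjust(p)
        assert np.allclose(ours, _bh_brute(p), atol=1e-12)
        assert np.allclose(ours, multipletests(p, method="fdr_bh")[1],
                           atol=1e-12)

    def test_monotone_on_sorted_input(self):
        p = np.sort(np.random.default_rng(5).uniform(size=200))
        adj = ig.bh_adjust(p)
        assert (np.diff(adj) >= -1e-15).all()


@pytest.fixture(scope="module")
def planted():
    """Two-group cohort: one subtype, 50 subtype-DE genes, effect 3,
    noise 0.5 — the whole planted signal should pass (0.05, 1.7)."""
    cfg = ig.SimConfig(n_case=30, n_ctrl=30, n_genes=600, k_subtypes=1,
                       subtype_props=(1.0,), n_de_per_subtype=50,
                       n_global_de=0, effect_size=3.0, noise_sd=0.5,
                       n_batches=1, batch_shift_sd=0.0, seed=4)
    return ig.generate_cohort(cfg)


class TestTwoGroupDegs:

    def test_planted_genes_recovered_without_false_positives(self, planted):
        expr, ann, truth = planted
        degs = ig.two_group_degs(expr, ann["group"], ig.DEGThresholds(0.05, 1.7),
                                 group1="case", group2="control")
        planted_set = set(truth.all_case_shifted_genes())
        found = set(degs["gene_id"])
        assert found == planted_set

    def test_null_gene_absent(self, planted):
        expr, ann, truth = planted
        degs = ig.two_group_degs(expr, ann["group"], ig.DEGThresholds(0.05, 0.0),
                                 group1="case", group2="control")
        null_genes = set(expr.index) - set(truth.all_case_shifted_genes())
        # a null gene with equal population means: none should dominate the list
        top10 = set(degs["gene_id"].head(10))
        assert not top10 & null_genes

    def test_unsatisfiable_lfc_gives_empty_list(self, planted):
        expr, ann, _ = planted
        degs = ig.two_group_degs(expr, ann["group"],
                                 ig.DEGThresholds(0.05, np.inf))
        assert degs.empty

    def test_swapping_groups_negates_log2fc(self, planted):
        expr, ann, _ = planted
        thr = ig.DEGThresholds(0.05, 1.7)
        a = ig.two_group_degs(expr, ann["group"], thr, group1="case",
                              group2="control").set_index("gene_id")
        b = ig.two_group_degs(expr, ann["group"], thr, group1="control",
                              group2="case").set_index("gene_id")
        common = a.index.intersection(b.index)
        assert len(common) == len(a)
        assert np.allclose(a.loc[common, "log2fc"], -b.loc[common, "log2fc"])
        assert np.allclose(a.loc[common, "p"], b.loc[common, "p"], atol=1e-12)

    def test_direction_matches_sign(self, planted):
        expr, ann, _ = planted
        degs = ig.two_group_degs(expr, ann["group"], ig.DEGThresholds(0.05, 1.7),
                                 group1="case", group2="control")
        assert ((degs["log2fc"] > 0) == (degs["direction"] == "up")).all()

    def test_small_group_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)),
                            columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            ig.two_group_degs(expr, ["x", "x", "y"], ig.DEGThresholds())


class TestSubtypeContrasts:
    def test_k2_reduces_to_two_group(self, adjusted, cohort):
        _, _, ann, truth = cohort
        cases = ann.loc[ann.group == "case", "sample_id"].tolist()
        labels = truth.true_subtype.loc[cases].to_numpy()
        merged = np.where(labels == 1, 1, 2)  # collapse to two subtypes
        thr = ig.DEGThresholds(0.01, 1.0)
        a = ig.subtype_vs_rest_degs(adjusted[cases], merged, 1, thr)
        b = ig.two_group_degs(adjusted[cases],
                              np.where(merged == 1, "t", "r"), thr,
                              group1="t", group2="r")
        pd.testing.assert_frame_equal(a, b)

    def test_planted_block_recovered_at_strict_thresholds(self, adjusted, cohort):
        _, _, ann, truth = cohort
        cases = ann.loc[ann.group == "case", "sample_id"].tolist()
        labels = truth.true_subtype.loc[cases].to_numpy()
        degs = ig.subtype_vs_rest_degs(adjusted[cases], labels, 1,
                                       ig.DEGThresholds(0.01, 2.0))
        found = set(degs["gene_id"])
        assert set(truth.true_de_genes[1]) <= found
        # genuinely null genes never pass; other planted blocks sit at a
        # true |log2fc| of half the effect and may graze the cutoff
        nulls = set(adjusted.index) - set(truth.all_case_shifted_genes())
        assert not found & nulls
        assert len(found - set(truth.true_de_genes[1])) <= 5

    def test_permuted_labels_yield_nothing(self, adjusted, cohort):
        _, _, ann, truth = cohort
        cases = ann.loc[ann.group == "case", "sample_id"].tolist()
        labels = truth.true_subtype.loc[cases].to_numpy()
        rng = np.random.default_rng(0)
        counts = []
        for _ in range(20):
            perm = rng.permutation(labels)
            degs = ig.subtype_vs_rest_degs(adjusted[cases], perm, 1,
                                           ig.DEGThresholds(0.01, 2.0))
            counts.append(len(degs))
        assert np.mean(counts) < 1.0

    def test_unknown_subtype_rejected(self, adjusted, cohort):
        _, _, ann, truth = cohort
        cases = ann.loc[ann.group == "case", "sample_id"].tolist()
        with pytest.raises(ValueError, match="unknown subtype"):
            ig.subtype_vs_rest_degs(adjusted[cases],
                                    truth.true_subtype.loc[cases].to_numpy(),
                                    9, ig.DEGThresholds())


class TestSubtypeSpecificGenes:
    @staticmethod
    def _deg_frame(genes, lfc=1.0):
        return pd.DataFrame({"gene_id": list(genes),
                             "log2fc": [lfc] * len(genes),
                             "p": 0.001, "adj_p": 0.01,
                             "direction": "up" if lfc > 0 else "down"})

    def test_set_algebra(self):
        out = ig.subtype_specific_genes(self._deg_frame(["A", "B", "C"]),
                                        self._deg_frame(["B", "C", "D"]))
        assert list(out["gene_id"]) == ["B", "C"]

    def test_disjoint_inputs_empty(self):
        out = ig.subtype_specific_genes(self._deg_frame(["A"]),
                                        self._deg_frame(["B"]))
        assert out.empty

    def test_subset_returns_subtype_list_with_its_direction(self):
        g = self._deg_frame(["A", "B", "C", "D"])
        s = self._deg_frame(["B", "C"], lfc=-2.0)
        out = ig.subtype_specific_genes(g, s)
        assert list(out["gene_id"]) == ["B", "C"]
        assert (out["direction"] == "down").all()


class TestGeneTraitCorrelation:
    def test_perfect_and_inverted_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        expr = pd.DataFrame([x, -x], index=["gpos", "gneg"],
                            columns=[f"S{i}" for i in range(30)])
        trait = pd.Series(x, index=expr.columns)
        out = ig.gene_trait_correlation(expr, trait).set_index("gene_id")
        assert out.loc["gpos", "r"] == pytest.approx(1.0)
        assert out.loc["gneg", "r"] == pytest.approx(-1.0)
        assert out["significant"].all()

    def test_constant_trait_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 10)),
                            columns=[f"S{i}" for i in range(10)])
        with pytest.raises(ValueError, match="constant"):
            ig.gene_trait_correlation(expr, pd.Series(1.0, index=expr.columns))

    def test_loaded_genes_flagged_unloaded_calibrated(self, cohort):
        _, expr, ann, truth = cohort
        traits = ig.generate_traits(expr, truth, ann, noise_sd=0.0, seed=0)
        cases = traits.index.tolist()
        loaded = list(truth.trait_loadings["eGFR_like"])
        rng = np.random.default_rng(3)
        unloaded = [g for g in expr.index
                    if g not in set(truth.all_case_shifted_genes())]
        probe = list(rng.choice(unloaded, size=200, replace=False))
        out = ig.gene_trait_correlation(expr[cases], traits["eGFR_like"],
                                        loaded + probe).set_index("gene_id")
        assert out.loc[loaded, "significant"].all()
        false_rate = out.loc[probe, "significant"].mean()
        # BH controls FDR; with no true signal among the probes the
        # significant fraction should sit near zero
        assert false_rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)
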