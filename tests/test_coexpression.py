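import numpy as np
import pandas as pd
import pytest

import igansub as ig
from igansub.coexpression import scale_free_fit


def _tom_brute(a):
    """Triple-loop topological overlap: the independent oracle."""
    n = a.shape[0]
    tom = np.eye(n)
    k = a.sum(axis=1) - np.diag(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def _random_adjacency(rng, n):
    m = rng.uniform(size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return m


@pytest.fixture(scope="module")
def blocks():
    """Two uncorrelated 50-gene blocks (within-block cor ~0.8) + noise."""
    rng = np.random.default_rng(10)
    n_samp = 60
    rows = []
    for _ in range(2):
        f = rng.normal(size=n_samp)
        c = 0.8
        for _ in range(50):
            rows.append(c * f + np.sqrt(1 - c * c) * rng.normal(size=n_samp))
    for _ in range(40):
        rows.append(rng.normal(size=n_samp))
    genes = [f"G{i:03d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=genes,
                        columns=[f"S{i}" for i in range(n_samp)])


class TestVarianceFilter:
    def test_counts(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(100, 10)),
                            index=[f"g{i}" for i in range(100)])
        assert ig.variance_filter(expr, 0.25).shape[0] == 25
        assert ig.variance_filter(expr, 1.0).equals(expr)

    def test_high_variance_block_retained(self):
        rng = np.random.default_rng(1)
        low = rng.normal(0, 1, size=(90, 20))
        high = rng.normal(0, np.sqrt(10), size=(10, 20))
        expr = pd.DataFrame(np.vstack([low, high]),
                            index=[f"g{i}" for i in range(100)])
        kept = ig.variance_filter(expr, 0.1)
        assert set(kept.index) == {f"g{i}" for i in range(90, 100)}

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            ig.variance_filter(pd.DataFrame(np.eye(3)), 0.0)


class TestSoftThreshold:
    def test_single_power_returned(self, blocks):
        beta, tab = ig.pick_soft_threshold(blocks, powers=(3,))
        assert beta == 3 and len(tab) == 1

    def test_fit_table_bookkeeping(self, blocks):
        _, tab = ig.pick_soft_threshold(blocks, powers=range(1, 7))
        assert len(tab) == 6
        assert list(tab["power"]) == [1, 2, 3, 4, 5, 6]

    def test_modular_cohort_reaches_target(self):
        expr, _ = ig.generate_modular_expression(
            module_sizes=(150, 150, 150), n_background=150, n_samples=80,
            seed=0)
        beta, tab = ig.pick_soft_threshold(expr, r2_target=0.9)
        chosen = tab.loc[tab.power == beta, "signed_r2"].iloc[0]
        assert chosen >= 0.9

    def test_constant_connectivity_rejected(self):
        with pytest.raises(ValueError):
            scale_free_fit(np.ones(50))

    def test_adjacency_beta1_is_absolute_correlation(self, blocks):
        a = ig.adjacency_matrix(blocks, 1).to_numpy()
        c = np.abs(np.corrcoef(blocks.to_numpy()))
        np.fill_diagonal(c, 1.0)
        assert np.allclose(a, c)


class TestTOM:
    def test_isolated_perfect_pair(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 1.0
        tom = ig.tom_transform(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_zero_offdiagonal_gives_zero_tom(self):
        tom = ig.tom_transform(np.eye(5))
        assert np.allclose(tom, np.eye(5))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(5, 11))
            a = _random_adjacency(rng, n)
            assert np.allclose(ig.tom_transform(a), _tom_brute(a), atol=1e-12)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a = _random_adjacency(rng, int(rng.integers(5, 11)))
            tom = ig.tom_transform(a)
            assert tom.min() >= -1e-12 and tom.max() <= 1 + 1e-12

    def test_asymmetric_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            ig.tom_transform(a)


class TestModules:
    def test_two_planted_blocks_found_pure(self, blocks):
        a = ig.adjacency_matrix(blocks, 3).to_numpy()
        tom = ig.tom_transform(a)
        mods = ig.detect_modules(tom, blocks.index, min_module_size=30)
        non_grey = mods.labels[mods.labels != ig.GREY]
        assert non_grey.nunique() == 2
        b1 = mods.labels.iloc[:50]
        b2 = mods.labels.iloc[50:100]
        assert b1.nunique() == 1 and b2.nunique() == 1
        assert b1.iloc[0] != b2.iloc[0]

    def test_min_size_above_n_gives_all_grey(self, blocks):
        tom = ig.tom_transform(ig.adjacency_matrix(blocks, 3).to_numpy())
        mods = ig.detect_modules(tom, blocks.index, min_module_size=1000)
        assert (mods.labels == ig.GREY).all()

    def test_gene_order_invariance(self, blocks):
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(blocks))
        shuffled = blocks.iloc[perm]
        tom1 = ig.tom_transform(ig.adjacency_matrix(blocks, 3).to_numpy())
        tom2 = ig.tom_transform(ig.adjacency_matrix(shuffled, 3).to_numpy())
        m1 = ig.detect_modules(tom1, blocks.index, 30).labels
        m2 = ig.detect_modules(tom2, shuffled.index, 30).labels
        # identical partition up to label names
        tab = pd.crosstab(m1.loc[blocks.index], m2.loc[blocks.index])
        assert ((tab > 0).sum(axis=1) == 1).all()


class TestEigengenes:
    def test_identical_genes_give_their_profile(self):
        rng = np.random.default_rng(5)
        profile = rng.normal(size=20)
        expr = pd.DataFrame([profile, profile, profile],
                            index=["a", "b", "c"],
                            columns=[f"S{i}" for i in range(20)])
        e = ig.module_eigengene(expr, ["a", "b", "c"])
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.corrcoef(e, z)[0, 1] == pytest.approx(1.0)

    def test_unit_variance_and_sign(self, blocks):
        e = ig.module_eigengene(blocks, blocks.index[:50])
        assert e.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        mean_profile = ig.zscore_genes(blocks.iloc[:50]).mean(axis=0)
        assert np.corrcoef(e, mean_profile)[0, 1] >= 0

    def test_pc1_explains_most_variance(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.normal(size=(10, 20)),
                            index=[f"g{i}" for i in range(10)],
                            columns=[f"S{i}" for i in range(20)])
        x = ig.zscore_genes(expr).to_numpy()
        s = np.linalg.svd(x, compute_uv=False)
        share = s[0] ** 2 / (s ** 2).sum()
        assert share >= 1 / 10  # no single gene's share exceeds PC1's


class TestMerging:
    def test_near_identical_modules_merge(self, blocks):
        labels = pd.Series(ig.GREY, index=blocks.index)
        # split one coherent block into two artificial modules
        labels.iloc[:25] = "m1"
        labels.iloc[25:50] = "m2"
        merged, eig = ig.merge_modules(blocks, labels, cut_height=0.25)
        non_grey = merged[merged != ig.GREY]
        assert non_grey.nunique() == 1

    def test_uncorrelated_modules_untouched(self, blocks):
        labels = pd.Series(ig.GREY, index=blocks.index)
        labels.iloc[:50] = "m1"
        labels.iloc[50:100] = "m2"
        merged, _ = ig.merge_modules(blocks, labels, cut_height=0.25)
        assert merged[merged != ig.GREY].nunique() == 2

    def test_never_increases_module_count(self, blocks):
        rng = np.random.default_rng(7)
        labels = pd.Series(rng.choice(["a", "b", "c", "d"], size=len(blocks)),
                           index=blocks.index)
        merged, _ = ig.merge_modules(blocks, labels, cut_height=0.25)
        assert merged.nunique() <= labels.nunique()


class TestModuleTraitAndHubs:
    def test_eigengene_equal_to_indicator(self):
        rng = np.random.default_rng(8)
        ind = np.tile([1.0, 0.0], 15)
        eig = pd.DataFrame([(ind - ind.mean()) / ind.std(ddof=1)],
                           index=["m1"], columns=[f"S{i}" for i in range(30)])
        traits = pd.DataFrame({"t": ind}, index=eig.columns)
        r, p = ig.module_trait_correlation(eig, traits)
        assert r.loc["m1", "t"] == pytest.approx(1.0)

    def test_random_trait_bounded_correlation(self, blocks):
        rng = np.random.default_rng(9)
        eig = ig.compute_eigengenes(
            blocks, pd.Series(["m1"] * 50 + ["m2"] * 50 + [ig.GREY] * 40,
                              index=blocks.index))
        traits = pd.DataFrame({"noise": rng.normal(size=blocks.shape[1])},
                              index=blocks.columns)
        r, _ = ig.module_trait_correlation(eig, traits)
        assert (r["noise"].abs() < 0.45).all()  # Fisher-z bound at n=60

    def test_hub_gates(self, blocks):
        labels = pd.Series([ig.GREY] * len(blocks), index=blocks.index)
        labels.iloc[:50] = "m1"
        eig = ig.compute_eigengenes(blocks, labels)
        # trait equal to the eigengene: block genes are hubs
        trait = pd.Series(eig.loc["m1"].to_numpy(), index=blocks.columns)
        mods = ig.mm_gs_hubs(blocks, labels, eig, trait)
        assert len(mods.hubs["m1"]) > 0
        assert set(mods.hubs["m1"]) <= set(labels.index[labels == "m1"])
        # a trait orthogonal by construction gates everything out
        ortho = pd.Series(np.tile([1.0, -1.0], 30) * 0.0, index=blocks.columns)
        with pytest.raises(ValueError):
            ig.module_trait_correlation(eig, pd.DataFrame({"t": ortho}))

    def test_zero_thresholds_admit_all_correlated_members(self, blocks):
        labels = pd.Series([ig.GREY] * len(blocks), index=blocks.index)
        labels.iloc[:50] = "m1"
        eig = ig.compute_eigengenes(blocks, labels)
        trait = pd.Series(np.random.default_rng(11).normal(size=blocks.shape[1]),
                          index=blocks.columns)
        mods = ig.mm_gs_hubs(blocks, labels, eig, trait, mm_thr=0.0, gs_thr=0.0)
        assert set(mods.hubs["m1"]) == set(labels.index[labels == "m1"])
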