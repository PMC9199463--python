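from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse, stats

from perimark.cluster import ClusterLabels
from perimark.io import CountMatrix
from perimark.markers import (
    bh_adjust,
    cross_tissue_venn,
    de_table,
    map_orthologs,
    pct3_per_gene,
    select_markers,
    wilcoxon_test,
)
from perimark.preprocess import log_normalize


def brute_force_wilcoxon_p(x, y):
    """Enumerate all C(n+m, n) group assignments of the pooled midranks."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, N = len(x), len(pooled)
    mean = n * (N + 1) / 2
    obs = ranks[:n].sum()
    dev = abs(obs - mean)
    hits = sum(
        1 for c in combinations(range(N), n)
        if abs(ranks[list(c)].sum() - mean) >= dev - 1e-9
    )
    return hits / comb(N, n)


class TestWilcoxon:
    def test_exact_separated_groups(self):
        _, p = wilcoxon_test([1, 2, 3], [4, 5, 6], mode="exact")
        assert p == pytest.approx(2 / 20)

    def test_all_tied_gives_p_one(self):
        for mode in ("exact", "normal"):
            _, p = wilcoxon_test([5, 5], [5, 5], mode=mode)
            assert p == 1.0

    def test_exact_equals_brute_force_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 4, rng.integers(2, 6)).astype(float)
            y = rng.integers(0, 4, rng.integers(2, 6)).astype(float)
            _, p = wilcoxon_test(x, y, mode="exact")
            assert p == pytest.approx(brute_force_wilcoxon_p(x, y), abs=1e-12)

    def test_normal_close_to_exact_at_balanced_sizes(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            _, pe = wilcoxon_test(x, y, mode="exact")
            _, pn = wilcoxon_test(x, y, mode="normal")
            assert pn == pytest.approx(pe, abs=0.02)

    def test_normal_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.integers(0, 6, 15).astype(float)
            y = rng.integers(0, 6, 25).astype(float)
            _, p = wilcoxon_test(x, y, mode="normal")
            sp = stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue
            assert p == pytest.approx(sp, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_test([], [1.0])


class TestBhAdjust:
    def test_step_up_examples(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust([0.005, 0.1]), [0.01, 0.1])
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_permutation_equivariance_and_bounds(self, ps):
        ps = np.array(ps)
        adj = bh_adjust(ps)
        assert ((adj >= ps - 1e-12) & (adj <= 1 + 1e-12)).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        np.testing.assert_allclose(bh_adjust(ps[perm]), adj[perm], atol=1e-12)

    def test_monotone_in_each_input(self):
        base = np.array([0.02, 0.5, 0.1, 0.9])
        adj0 = bh_adjust(base)
        bumped = base.copy()
        bumped[2] = 0.2
        adj1 = bh_adjust(bumped)
        assert (adj1 >= adj0 - 1e-12).all()


def random_fixture(rng, n_genes=8, n_clusters=4, cells_per=6):
    labels = ClusterLabels(np.repeat(np.arange(n_clusters), cells_per))
    dense = rng.poisson(0.8, size=(n_genes, n_clusters * cells_per))
    counts = CountMatrix(
        sparse.csr_matrix(dense),
        [f"g{i}" for i in range(n_genes)],
        [f"c{j}" for j in range(n_clusters * cells_per)],
    )
    return counts, labels


class TestPct3:
    def test_max_over_non_enriched(self):
        # gene expressed in 50% of cluster 1 cells, 10% of cluster 2 cells
        dense = np.zeros((1, 30), dtype=int)
        dense[0, 10:15] = 1          # cluster 1: 5/10
        dense[0, 20:21] = 1          # cluster 2: 1/10
        counts = CountMatrix(sparse.csr_matrix(dense), ["g"],
                             [f"c{j}" for j in range(30)])
        labels = ClusterLabels(np.repeat([0, 1, 2], 10))
        assert pct3_per_gene(counts, labels, {0})[0] == pytest.approx(0.5)

    def test_silent_gene_is_zero(self):
        counts = CountMatrix(sparse.csr_matrix((2, 10), dtype=np.int64),
                             ["a", "b"], [f"c{j}" for j in range(10)])
        labels = ClusterLabels(np.repeat([0, 1], 5))
        assert (pct3_per_gene(counts, labels, {0}) == 0).all()

    def test_all_enriched_rejected(self):
        counts = CountMatrix(sparse.csr_matrix((1, 4), dtype=np.int64),
                             ["a"], list("wxyz"))
        labels = ClusterLabels(np.repeat([0, 1], 2))
        with pytest.raises(ValueError, match="enriched"):
            pct3_per_gene(counts, labels, {0, 1})

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts, labels = random_fixture(rng)
            enriched = {0}
            got = pct3_per_gene(counts, labels, enriched)
            dense = np.asarray(counts.values.todense())
            for g in range(counts.n_genes):
                expected = 0.0
                for c in range(labels.n_clusters):
                    if c in enriched:
                        continue
                    members = labels.members(c)
                    frac = sum(dense[g, j] > 0 for j in members) / len(members)
                    expected = max(expected, frac)
                assert got[g] == expected


@pytest.fixture(scope="module")
def de_fixture():
    rng = np.random.default_rng(5)
    n_cells = 60
    labels = ClusterLabels(np.repeat([0, 1, 2], 20))
    mask = np.zeros(n_cells, bool)
    mask[:10] = True             # stringent cells inside cluster 0
    dense = rng.poisson(1.0, size=(6, n_cells))
    dense[0] = 3                 # identical everywhere
    dense[1, :10] = [1, 2, 0, 3, 1, 1, 2, 0, 3, 1]   # pct1 = 0.8
    dense[2, :10] = 9            # strong marker
    dense[2, 10:] = 0
    # balance column sums so normalization keeps g0 identical in all cells
    dense[5] = dense.sum(axis=0).max() - dense[:5].sum(axis=0)
    counts = CountMatrix(sparse.csr_matrix(dense),
                         [f"g{i}" for i in range(6)],
                         [f"c{j}" for j in range(n_cells)])
    norm = log_normalize(counts)
    return de_table(norm, counts, mask, labels, {0}), counts


class TestDeTable:
    def test_identical_gene_null(self, de_fixture):
        table, _ = de_fixture
        row = table[table["gene"] == "g0"].iloc[0]
        assert row["p"] == pytest.approx(1.0, abs=1e-9)
        assert row["avg_log2fc"] == pytest.approx(0.0, abs=1e-9)

    def test_pct1_from_raw_counts(self, de_fixture):
        table, _ = de_fixture
        assert table.set_index("gene").loc["g1", "pct1"] == pytest.approx(0.8)

    def test_strong_marker_significant(self, de_fixture):
        table, _ = de_fixture
        row = table.set_index("gene").loc["g2"]
        assert row["p_adj"] < 0.05
        assert row["pct1"] == 1.0
        assert row["pct2"] == 0.0
        assert row["avg_log2fc"] > 1

    def test_too_few_cells_rejected(self, de_fixture):
        _, counts = de_fixture
        labels = ClusterLabels(np.repeat([0, 1, 2], 20))
        mask = np.zeros(60, bool)
        mask[0] = True
        with pytest.raises(ValueError, match="cells per group"):
            de_table(log_normalize(counts), counts, mask, labels, {0})

    def test_p_values_match_scalar_wilcoxon(self, de_fixture):
        table, counts = de_fixture
        norm = log_normalize(counts)
        mask = np.zeros(60, bool)
        mask[:10] = True
        dense = np.asarray(norm.values.todense())
        for gene in ("g1", "g2", "g4"):
            g = counts.gene_index(gene)
            _, p_scalar = wilcoxon_test(dense[g, mask], dense[g, ~mask], "normal")
            p_table = table.set_index("gene").loc[gene, "p"]
            assert p_table == pytest.approx(p_scalar, abs=1e-12)


class TestSelectMarkers:
    @pytest.mark.parametrize(
        "p_adj, pct1, pct2, pct3, selected, high_spec",
        [
            (0.04, 0.85, 0.03, 0.5, True, False),
            (0.04, 0.80, 0.03, 0.05, False, False),   # pct1 strict
            (0.05, 0.85, 0.03, 0.05, False, False),   # alpha strict
            (0.04, 0.85, 0.05, 0.05, False, False),   # pct2 strict
            (0.04, 0.85, 0.03, 0.09, True, True),
            (0.04, 0.85, 0.03, 0.10, True, False),    # pct3 strict
        ],
    )
    def test_strict_thresholds(self, p_adj, pct1, pct2, pct3, selected, high_spec):
        table = pd.DataFrame({
            "gene": ["g"], "avg_log2fc": [1.0], "p": [p_adj / 2],
            "p_adj": [p_adj], "pct1": [pct1], "pct2": [pct2], "pct3": [pct3],
            "selected": [False], "high_specificity": [False],
        })
        out = select_markers(table)
        assert bool(out.loc[0, "selected"]) is selected
        assert bool(out.loc[0, "high_specificity"]) is high_spec


class TestCrossTissueVenn:
    def test_shared_patterns(self):
        sets = {
            "lung": {"Higd1b", "Cox4i2", "Kcnk3"},
            "heart": {"Higd1b", "Rgs4"},
            "kidney": {"Cox4i2", "Myh11"},
            "bladder": {"Cox4i2", "Pcp4l1"},
        }
        venn = cross_tissue_venn(sets)
        assert "Higd1b" in venn[frozenset({"lung", "heart"})]
        assert "Cox4i2" in venn[frozenset({"lung", "kidney", "bladder"})]

    def test_disjoint_sets_are_singleton_patterns(self):
        sets = {"a": {"x"}, "b": {"y", "z"}}
        venn = cross_tissue_venn(sets)
        assert set(venn) == {frozenset({"a"}), frozenset({"b"})}
        assert sum(len(v) for v in venn.values()) == 3

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.sets(st.integers(0, 30)), min_size=2, max_size=4))
    def test_partition_conserves_union(self, raw_sets):
        sets = {f"t{i}": {str(g) for g in s} for i, s in enumerate(raw_sets)}
        union = set().union(*sets.values())
        if not union:
            return
        venn = cross_tissue_venn(sets)
        assert sum(len(v) for v in venn.values()) == len(union)
        for pattern, genes in venn.items():
            for g in genes:
                assert {t for t, s in sets.items() if g in s} == set(pattern)


def test_ortholog_map_uppercases():
    assert map_orthologs(["Higd1b", "Notch3"]) == {
        "Higd1b": "HIGD1B", "Notch3": "NOTCH3"
    }
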