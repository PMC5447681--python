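"""Adjacency, topological overlap, connectivity, and the permutation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from altinet import (
    DifferentialConnectivity,
    SimConfig,
    adjacency,
    connectivity,
    export_edges,
    simulate_coexpression,
    tom,
)
from altinet.network import AdjacencyMatrix, TOMatrix


def brute_force_tom(a):
    """Independent triple-loop oracle for the topological overlap matrix."""
    n = len(a)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            t[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return t


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(gene_ids=[f"g{i}" for i in range(n)], a=a, beta=1.0)


class TestAdjacency:
    def test_perfect_correlation_gives_unit_adjacency(self):
        x = pd.DataFrame(
            [[1.0, 2, 3, 4, 5], [2, 4, 6, 8, 10], [5, 4, 3, 2, 1]],
            index=["g0", "g1", "g2"],
        )
        adj = adjacency(x, beta=6.0)
        assert adj.a[0, 1] == pytest.approx(1.0)
        assert adj.a[0, 2] == pytest.approx(1.0)  # anti-correlation, unsigned

    def test_beta_one_equals_abs_correlation(self, rng):
        x = pd.DataFrame(rng.normal(size=(6, 20)), index=[f"g{i}" for i in range(6)])
        adj = adjacency(x, beta=1.0)
        c = np.abs(np.corrcoef(x.to_numpy()))
        np.fill_diagonal(c, 0.0)
        np.testing.assert_allclose(adj.a, c, atol=1e-12)

    def test_matches_pairwise_brute_force(self, rng):
        x = pd.DataFrame(rng.normal(size=(6, 20)), index=[f"g{i}" for i in range(6)])
        adj = adjacency(x, beta=6.0)
        xv = x.to_numpy()
        for i in range(6):
            for j in range(i + 1, 6):
                r = stats.pearsonr(xv[i], xv[j]).statistic
                assert adj.a[i, j] == pytest.approx(abs(r) ** 6, abs=1e-12)

    def test_zero_variance_gene_excluded_with_warning(self, rng):
        x = pd.DataFrame(rng.normal(size=(4, 10)), index=list("abcd"))
        x.loc["c"] = 3.14
        with pytest.warns(UserWarning, match="zero-variance"):
            adj = adjacency(x, beta=2.0)
        assert adj.gene_ids == ["a", "b", "d"]


class TestTom:
    def test_two_gene_closed_form(self):
        for a12 in (0.0, 0.3, 0.9, 1.0):
            adj = AdjacencyMatrix(["g0", "g1"], np.array([[0, a12], [a12, 0.0]]), 1.0)
            t = tom(adj)
            assert t.t[0, 1] == pytest.approx(a12)

    def test_complete_triangle_is_fully_overlapping(self):
        a = np.ones((3, 3)) - np.eye(3)
        t = tom(AdjacencyMatrix(["g0", "g1", "g2"], a, 1.0))
        np.testing.assert_allclose(t.t, 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(5):
            adj = random_adjacency(rng, 8)
            t = tom(adj)
            np.testing.assert_allclose(t.t, brute_force_tom(adj.a), atol=1e-12)

    def test_bounds_and_symmetry_on_random_matrices(self, rng):
        for _ in range(20):
            adj = random_adjacency(rng, 10)
            t = tom(adj).t
            assert np.allclose(t, t.T)
            assert (t >= -1e-12).all() and (t <= 1 + 1e-12).all()
            assert np.allclose(np.diag(t), 1.0)


class TestConnectivity:
    def test_three_gene_example(self):
        a = np.array([[0, 0.5, 0.2], [0.5, 0, 0.0], [0.2, 0.0, 0]])
        k = connectivity(AdjacencyMatrix(["g0", "g1", "g2"], a, 1.0))
        np.testing.assert_allclose(k["k"], [0.7, 0.5, 0.2])
        np.testing.assert_allclose(k["normalized_k"], [1.0, 5 / 7, 2 / 7])

    def test_empty_network_has_zero_connectivity(self):
        a = np.zeros((3, 3))
        k = connectivity(AdjacencyMatrix(["g0", "g1", "g2"], a, 1.0))
        assert (k["k"] == 0).all() and (k["normalized_k"] == 0).all()

    def test_tom_connectivity_equals_row_sum_minus_diagonal(self, rng):
        adj = random_adjacency(rng, 7)
        t = tom(adj)
        k = connectivity(t)
        for i, g in enumerate(t.gene_ids):  # brute-force row sums
            expected = sum(t.t[i, j] for j in range(7) if j != i)
            assert k.loc[g, "k"] == pytest.approx(expected, abs=1e-12)

    def test_adjacency_connectivity_is_sum_of_abs_correlations_at_beta_one(self, rng):
        x = pd.DataFrame(rng.normal(size=(5, 30)), index=[f"g{i}" for i in range(5)])
        k = connectivity(adjacency(x, beta=1.0))
        c = np.abs(np.corrcoef(x.to_numpy()))
        for i in range(5):
            expected = sum(c[i, j] for j in range(5) if j != i)
            assert k.iloc[i]["k"] == pytest.approx(expected, abs=1e-10)


class TestExportEdges:
    def test_threshold_zero_writes_all_pairs(self, rng, tmp_path):
        t = tom(random_adjacency(rng, 6))
        n = export_edges(t, 0.0, tmp_path / "e.tsv")
        assert n == 6 * 5 // 2
        lines = (tmp_path / "e.tsv").read_text().splitlines()
        assert lines[0] == "gene_a\tgene_b\tweight"
        assert len(lines) == n + 1

    def test_single_edge_above_threshold(self, tmp_path):
        a = np.array([[0, 0.9, 0.1], [0.9, 0, 0.1], [0.1, 0.1, 0]])
        t = TOMatrix(["g0", "g1", "g2"], a)
        n = export_edges(t, 0.5, tmp_path / "e.tsv")
        assert n == 1
        assert (tmp_path / "e.tsv").read_text().splitlines()[1].startswith("g0\tg1")

    def test_bad_threshold_rejected(self, rng, tmp_path):
        with pytest.raises(ValueError):
            export_edges(tom(random_adjacency(rng, 4)), 1.5, tmp_path / "e.tsv")


class TestDifferentialConnectivity:
    def test_identical_groups_give_zero_diffs_and_no_calls(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 12)), index=[f"g{i}" for i in range(30)])
        res = DifferentialConnectivity(x, x.copy(), beta=6).fit(n_perm=50, seed=0)
        np.testing.assert_allclose(res.table["diff"], 0.0, atol=1e-12)
        assert not res.table["significant"].any()

    def test_seed_reproducibility(self):
        cfg = SimConfig(n_genes=40, module_size=5, coexpr_n_samples=10, seed=2)
        x1, x2, _ = simulate_coexpression(cfg)
        r1 = DifferentialConnectivity(x1, x2).fit(n_perm=60, seed=9)
        r2 = DifferentialConnectivity(x1, x2).fit(n_perm=60, seed=9)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_too_few_permutations_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(10, 8)))
        with pytest.raises(ValueError, match="n_perm"):
            DifferentialConnectivity(x, x).fit(n_perm=10)

    def test_mismatched_gene_sets_rejected(self, rng):
        x1 = pd.DataFrame(rng.normal(size=(5, 8)), index=list("abcde"))
        x2 = pd.DataFrame(rng.normal(size=(5, 8)), index=list("abcdf"))
        with pytest.raises(ValueError, match="gene set"):
            DifferentialConnectivity(x1, x2)

    def test_perm_p_bounds(self):
        cfg = SimConfig(n_genes=50, module_size=8, coexpr_n_samples=10, seed=5)
        x1, x2, _ = simulate_coexpression(cfg)
        res = DifferentialConnectivity(x1, x2).fit(n_perm=99, seed=1)
        p = res.table["perm_p"]
        assert (p >= 1 / 100).all() and (p <= 1.0).all()

    def test_null_p_values_are_approximately_uniform(self):
        """Pooled permutation p-values under an exchangeable null pass a KS
        check against uniformity at alpha = 0.01."""
        pooled = []
        for rep in range(4):
            cfg = SimConfig(n_genes=100, module_latent_sd=0.0,
                            coexpr_n_samples=16, seed=300 + rep)
            x1, x2, _ = simulate_coexpression(cfg)
            res = DifferentialConnectivity(x1, x2).fit(n_perm=199, seed=rep)
            pooled.extend(res.table["perm_p"].tolist())
        ks = stats.kstest(pooled, "uniform")
        assert ks.pvalue > 0.01
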