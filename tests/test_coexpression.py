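import numpy as np
import pandas as pd
import pytest

from limbatlas.coexpression import (
    UNASSIGNED,
    CoexpressionModules,
    CoexprParams,
    activity_by_group,
    export_module_graph,
    iterative_module_discovery,
    module_activity,
    module_eigengenes,
    module_membership,
    signed_adjacency,
    static_tree_cut,
    topological_overlap,
)


def _expr(n_genes, n_cells, seed=0):
    return np.random.default_rng(seed).normal(size=(n_genes, n_cells))


class TestSignedAdjacency:
    def test_matches_elementwise_formula_on_toy(self):
        X = _expr(5, 30, seed=1)
        adj = signed_adjacency(X, beta=8.0)
        for i in range(5):
            for j in range(5):
                r = np.corrcoef(X[i], X[j])[0, 1]
                assert np.isclose(adj[i, j], ((1 + r) / 2) ** 8, atol=1e-8)

    def test_self_adjacency_is_one(self):
        adj = signed_adjacency(_expr(4, 10), beta=8.0)
        assert np.allclose(np.diag(adj), 1.0)

    def test_perfect_anticorrelation_vanishes(self):
        x = np.arange(10.0)
        X = np.vstack([x, -x])
        adj = signed_adjacency(X, beta=8.0)
        assert np.isclose(adj[0, 1], 0.0, atol=1e-12)

    def test_too_few_cells_or_constant_genes_raise(self):
        with pytest.raises(ValueError):
            signed_adjacency(_expr(3, 2))
        X = _expr(3, 10)
        X[1] = 5.0
        with pytest.raises(ValueError, match="constant"):
            signed_adjacency(X)


class TestTopologicalOverlap:
    def test_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        A = rng.random((6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = topological_overlap(A)
        n = 6
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(
                    A[i, u] * A[u, j] for u in range(n) if u not in (i, j)
                )
                k_i = sum(A[i, u] for u in range(n) if u != i)
                k_j = sum(A[j, u] for u in range(n) if u != j)
                expected = (shared + A[i, j]) / (min(k_i, k_j) + 1 - A[i, j])
                assert np.isclose(tom[i, j], expected, atol=1e-8)

    def test_two_gene_closed_form(self):
        a = 0.37
        A = np.array([[1.0, a], [a, 1.0]])
        tom = topological_overlap(A)
        assert np.isclose(tom[0, 1], a, atol=1e-12)

    def test_complete_graph_saturates(self):
        A = np.ones((5, 5))
        assert np.allclose(topological_overlap(A), 1.0)

    def test_symmetry_and_range_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            A = rng.random((8, 8))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            tom = topological_overlap(A)
            assert np.allclose(tom, tom.T)
            assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestStaticTreeCut:
    def _two_block_diss(self, n1, n2):
        n = n1 + n2
        D = np.ones((n, n))
        D[:n1, :n1] = 0.0
        D[n1:, n1:] = 0.0
        np.fill_diagonal(D, 0.0)
        return D

    def test_two_perfect_blocks(self):
        labels = static_tree_cut(self._two_block_diss(5, 4), 0.5, 2)
        assert len(set(labels)) == 2
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_branch_below_min_size_unassigned(self):
        labels = static_tree_cut(self._two_block_diss(14, 20), 0.5, 15)
        assert (labels[:14] == UNASSIGNED).all()
        assert (labels[14:] != UNASSIGNED).all()

    def test_labels_ranked_by_size(self):
        labels = static_tree_cut(self._two_block_diss(4, 7), 0.5, 2)
        assert labels[4] == "turquoise" and labels[0] == "blue"

    def test_no_branch_meets_min_size(self):
        D = 1 - np.eye(6)  # everything maximally dissimilar
        labels = static_tree_cut(D, 0.5, 3)
        assert (labels == UNASSIGNED).all()


class TestEigengenes:
    def test_identical_genes_give_standardized_profile(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=40)
        X = np.vstack([base, base, base])
        eig = module_eigengenes(X, ["turquoise"] * 3)
        expected = (base - base.mean()) / base.std()
        assert np.allclose(np.abs(eig["turquoise"]), np.abs(expected), atol=1e-8)
        # orientation makes it the positive version
        assert np.corrcoef(eig["turquoise"], base)[0, 1] > 0

    def test_orientation_nonnegative_with_mean_profile(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 30))
        assign = ["turquoise"] * 3 + ["blue"] * 3
        eig = module_eigengenes(X, assign)
        for module, rows in (("turquoise", slice(0, 3)), ("blue", slice(3, 6))):
            sub = X[rows]
            Z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
            assert np.corrcoef(eig[module], Z.mean(0))[0, 1] >= 0

    def test_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(4, 25))
        eig = module_eigengenes(X, ["blue"] * 4)["blue"].to_numpy()
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        U, S, Vt = np.linalg.svd(Z.T, full_matrices=False)
        ref = U[:, 0] / U[:, 0].std()
        assert np.allclose(np.abs(eig), np.abs(ref), atol=1e-8)
        assert np.isclose(eig.std(), 1.0)

    def test_single_gene_module(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(2, 20))
        eig = module_eigengenes(X, ["turquoise", "blue"])
        z = (X[1] - X[1].mean()) / X[1].std()
        assert np.allclose(eig["blue"], z, atol=1e-8)

    def test_constant_module_zero_eigengene(self):
        X = np.vstack([np.full(10, 3.0), np.full(10, 5.0)])
        eig = module_eigengenes(X, ["turquoise"] * 2)
        assert np.allclose(eig["turquoise"], 0.0)


class TestMembership:
    def test_uncorrelated_gene_has_p_one(self):
        n = 50
        eig = pd.DataFrame({"turquoise": np.sin(np.arange(n))})
        x = np.cos(np.arange(n))
        # orthogonalize exactly against the centered eigengene
        e = eig["turquoise"] - eig["turquoise"].mean()
        x = x - x.mean()
        x = x - (x @ e) / (e @ e) * e.to_numpy()
        kme, pv = module_membership(x[None, :], eig)
        assert np.isclose(kme.iloc[0, 0], 0.0, atol=1e-10)
        assert np.isclose(pv.iloc[0, 0], 1.0, atol=1e-8)

    def test_member_of_identical_module_has_unit_kme(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=30)
        X = np.vstack([base, base])
        eig = module_eigengenes(X, ["turquoise"] * 2)
        kme, pv = module_membership(X, eig)
        assert np.allclose(kme["turquoise"], 1.0, atol=1e-10)
        assert np.allclose(pv["turquoise"], 0.0)

    def test_p_value_matches_pearsonr_oracle(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(9)
        n = 100
        e = rng.normal(size=n)
        x = 0.5 * e + rng.normal(size=n)
        kme, pv = module_membership(x[None, :], pd.DataFrame({"m": e}))
        r_ref, p_ref = pearsonr(x, e)
        assert np.isclose(kme.iloc[0, 0], r_ref, atol=1e-10)
        assert np.isclose(pv.iloc[0, 0], p_ref, rtol=1e-8)

    def test_closed_form_at_r_half_n_100(self):
        from scipy.stats import t as t_dist

        # an exact r = 0.5 configuration via two standardized vectors
        n = 100
        rng = np.random.default_rng(10)
        e = rng.normal(size=n)
        e = (e - e.mean()) / e.std()
        z = rng.normal(size=n)
        z = z - z.mean()
        z -= (z @ e) / (e @ e) * e
        z = z / z.std() * np.sqrt(1 - 0.25)
        x = 0.5 * e + z
        kme, pv = module_membership(x[None, :], pd.DataFrame({"m": e}))
        t = 0.5 * np.sqrt((n - 2) / (1 - 0.25))
        assert np.isclose(kme.iloc[0, 0], 0.5, atol=1e-10)
        assert np.isclose(pv.iloc[0, 0], 2 * t_dist.sf(t, n - 2), rtol=1e-10)


class TestIterativeDiscovery:
    def test_fixed_point_terminates_in_one_iteration(self):
        rng = np.random.default_rng(11)
        f1, f2 = rng.normal(size=30), rng.normal(size=30)
        X = np.vstack(
            [f1 + 0.1 * rng.normal(size=(10, 30)),
             f2 + 0.1 * rng.normal(size=(10, 30))]
        )
        ms = iterative_module_discovery(X, CoexprParams(min_module_size=5,
                                                        cut_height=0.9))
        assert len(ms.iterations) == 1
        assert ms.iterations[0]["n_discarded"] == 0
        assert len(ms.module_labels) == 2

    def test_first_pass_uses_configured_min_size(self, module_atlas_prepared):
        _, truth, cmf, nm, mask = module_atlas_prepared
        from limbatlas.qc_norm import select_variable_genes

        hvg = set(select_variable_genes(nm))
        nm_h = nm.subset_genes([i for i, g in enumerate(nm.gene_ids) if g in hvg])
        ms = iterative_module_discovery(nm_h, CoexprParams())
        assert ms.iterations[0]["min_size"] == 15

    def test_planted_modules_recovered(self, module_atlas_prepared):
        _, truth, cmf, nm, mask = module_atlas_prepared
        from limbatlas.qc_norm import select_variable_genes

        hvg = set(select_variable_genes(nm))
        nm_h = nm.subset_genes([i for i, g in enumerate(nm.gene_ids) if g in hvg])
        ms = iterative_module_discovery(nm_h, CoexprParams())
        assert len(ms.iterations) <= 10
        assert len(ms.module_labels) == 3
        for i, planted in enumerate(truth.module_gene_sets):
            visible = {g for g in planted if g in hvg}
            best, jac = None, 0.0
            for m in ms.module_labels:
                got = set(ms.genes_of(m))
                j = len(got & visible) / len(got | visible)
                if j > jac:
                    best, jac = m, j
            assert jac >= 0.8
            f = truth.module_factor[mask, i]
            assert abs(np.corrcoef(ms.eigengenes[best], f)[0, 1]) >= 0.9
        # stopping rule: every retained gene significant for some module
        assert (ms.membership_p.min(axis=1) <= 0.01).all()

    def test_retained_set_monotone(self, module_atlas_prepared):
        _, truth, cmf, nm, mask = module_atlas_prepared
        from limbatlas.qc_norm import select_variable_genes

        hvg = set(select_variable_genes(nm))
        nm_h = nm.subset_genes([i for i, g in enumerate(nm.gene_ids) if g in hvg])
        ms = iterative_module_discovery(nm_h, CoexprParams())
        retained = [h["n_retained"] for h in ms.iterations]
        assert all(a >= b for a, b in zip(retained, retained[1:]))

    def test_sklearn_estimator_surface(self):
        rng = np.random.default_rng(12)
        f = rng.normal(size=40)
        X = f + 0.2 * rng.normal(size=(8, 40))
        est = CoexpressionModules(min_module_size=4, cut_height=0.9).fit(X.T)
        assert set(est.assignment_.unique()) == {"turquoise"}
        assert est.eigengenes_.shape == (40, 1)


class TestActivity:
    def test_single_gene_module_equals_gene(self):
        rng = np.random.default_rng(13)
        X = rng.random((3, 12))
        act = module_activity(X, ["turquoise", UNASSIGNED, UNASSIGNED])
        assert np.allclose(act["turquoise"], X[0])

    def test_all_zero_cell_has_zero_activity(self):
        X = np.ones((4, 5))
        X[:, 2] = 0.0
        act = module_activity(X, ["turquoise"] * 4)
        assert act["turquoise"].iloc[2] == 0.0

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(14)
        X = rng.random((6, 10))
        assign = ["turquoise"] * 4 + ["blue"] * 2
        act = module_activity(X, assign)
        assert np.allclose(act["turquoise"], X[:4].mean(axis=0), atol=1e-12)
        assert np.allclose(act["blue"], X[4:].mean(axis=0), atol=1e-12)

    def test_missing_genes_skipped_but_empty_module_errors(self):
        X = np.ones((2, 4))
        assign = pd.Series({"g0": "turquoise", "g1": "turquoise", "gX": "blue"})
        from types import SimpleNamespace

        nm = SimpleNamespace(values=X, gene_ids=["g0", "g1"], barcodes=list("abcd"))
        with pytest.raises(ValueError, match="blue"):
            module_activity(nm, assign)


class TestActivityByGroup:
    def test_single_group_grand_mean(self):
        rng = np.random.default_rng(15)
        act = pd.DataFrame({"turquoise": rng.random(8)})
        mat, _, _ = activity_by_group(act, [("HH29", 0)] * 8)
        assert np.isclose(mat.loc["turquoise", ("HH29", 0)],
                          act["turquoise"].mean())

    def test_identical_cells_groups_equal_cell_values(self):
        act = pd.DataFrame({"m": [2.0, 2.0, 7.0, 7.0]})
        mat, _, _ = activity_by_group(
            act, [("a", 0), ("a", 0), ("a", 1), ("a", 1)]
        )
        assert mat.loc["m", ("a", 0)] == 2.0 and mat.loc["m", ("a", 1)] == 7.0

    def test_group_means_match_groupby_oracle(self):
        rng = np.random.default_rng(16)
        act = pd.DataFrame({"x": rng.random(30), "y": rng.random(30)})
        groups = [("s1", i % 3) for i in range(15)] + [("s2", i % 2) for i in range(15)]
        mat, row_order, col_order = activity_by_group(act, groups)
        ref = act.groupby(pd.MultiIndex.from_tuples(groups)).mean().T
        assert np.allclose(mat.to_numpy(), ref.to_numpy())
        assert sorted(row_order.tolist()) == list(range(mat.shape[0]))
        assert sorted(col_order.tolist()) == list(range(mat.shape[1]))


class TestExportGraph:
    def _module_set(self, n=6, seed=17):
        rng = np.random.default_rng(seed)
        f = rng.normal(size=50)
        X = f + 0.3 * rng.normal(size=(n, 50))
        return iterative_module_discovery(
            X, CoexprParams(min_module_size=3, cut_height=0.9)
        )

    def test_top_n_equals_module_size_gives_all_genes(self):
        ms = self._module_set()
        m = ms.module_labels[0]
        nodes, edges = export_module_graph(ms, module=m)
        assert set(nodes["gene"]) == set(ms.genes_of(m))

    def test_every_node_keeps_a_visible_edge(self):
        ms = self._module_set(n=20, seed=18)
        m = ms.module_labels[0]
        nodes, edges = export_module_graph(ms, module=m)
        vis = edges[edges["visible"]]
        touched = set(vis["source"]) | set(vis["target"])
        assert touched == set(nodes["gene"])

    def test_equal_adjacency_gives_equal_scaled_weights(self):
        ms = self._module_set()
        m = ms.module_labels[0]
        genes = ms.genes_of(m)[:3]
        adj = pd.DataFrame(0.5, index=genes, columns=genes)
        sub = ms.assignment[ms.assignment.index.isin(genes)]
        ms2 = ms
        ms2.assignment = sub
        nodes, edges = export_module_graph(ms2, adj=adj, module=m)
        assert np.allclose(edges["scaled_weight"], 1.0)

    def test_unknown_module_raises(self):
        ms = self._module_set()
        with pytest.raises(KeyError):
            export_module_graph(ms, module="nope")
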