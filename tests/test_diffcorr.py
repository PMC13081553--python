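"""Differential correlation: Spearman matrices, candidates, permutation null, network."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from budsig import diffcorr


def _frame(arr, prefix="g", cases=None):
    arr = np.asarray(arr, dtype=float)
    cases = cases or [f"C{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=cases, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


def _within_pairing(a, b):
    fa, fb = _frame(a), _frame(b)
    return diffcorr.CompartmentPairing("tumor-tumor", a_x=fa, a_y=fa, b_x=fb, b_y=fb)


class TestConditionCorrelations:
    def test_monotone_pair_rho_one(self):
        a = np.column_stack([np.arange(8.0), np.exp(np.arange(8.0))])
        rho, _ = diffcorr.condition_correlations(_within_pairing(a, a), "A")
        assert rho.loc["g0", "g1"] == pytest.approx(1.0)

    def test_matches_rank_then_pearson_bruteforce(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 4))
        rho, p = diffcorr.condition_correlations(_within_pairing(a, a), "A")
        for i in range(4):
            for j in range(i + 1, 4):
                expect = stats.spearmanr(a[:, i], a[:, j])
                assert rho.iloc[i, j] == pytest.approx(expect.statistic)
                assert p.iloc[i, j] == pytest.approx(expect.pvalue, rel=1e-6)

    def test_constant_gene_recorded_missing(self):
        a = np.column_stack([np.ones(6), np.arange(6.0)])
        rho, _ = diffcorr.condition_correlations(_within_pairing(a, a), "A")
        assert np.isnan(rho.loc["g0", "g1"])

    def test_minimum_cases_enforced(self):
        a = np.random.default_rng(0).normal(size=(4, 3))
        with pytest.raises(ValueError, match=">= 5"):
            diffcorr.condition_correlations(_within_pairing(a, a), "A")


class TestCandidatePairs:
    def test_rho_exactly_point_eight_excluded(self):
        # construct a pair whose sample Spearman is exactly 0.8: n=5,
        # permutation [0,1,2,4,3] gives rho = 1 - 6*2/(5*24) = 0.9; use
        # rank data directly to place rho at the boundary via d^2 = 4
        x = np.arange(10.0)
        y = x.copy(); y[[0, 2]] = y[[2, 0]]  # d^2 = 8, n=10 -> rho = 1-48/990
        rho = stats.spearmanr(x, y).statistic
        assert rho < 0.96  # sanity
        a = np.column_stack([x, y])
        pairing = _within_pairing(a, np.random.default_rng(3).normal(size=(10, 2)))
        cands = diffcorr.candidate_pairs(pairing, rho_min=rho, fdr=1.0)
        # boundary: |rho| must be strictly above rho_min
        assert cands.empty

    def test_pair_significant_only_in_condition_b_included(self):
        rng = np.random.default_rng(4)
        n = 20
        x = rng.normal(size=n)
        b = np.column_stack([x, x + rng.normal(0, 0.05, n)])  # tight in B
        a = rng.normal(size=(n, 2))  # null in A
        pairing = _within_pairing(a, b)
        cands = diffcorr.candidate_pairs(pairing)
        assert len(cands) == 1

    def test_matches_loop_reimplementation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(15, 5))
        b = rng.normal(size=(15, 5))
        a[:, 1] = a[:, 0] + rng.normal(0, 0.05, 15)  # planted in A
        pairing = _within_pairing(a, b)
        cands = diffcorr.candidate_pairs(pairing, rho_min=0.8, fdr=0.01)
        # brute force: BH within condition over the 10 unordered pairs
        from statsmodels.stats.multitest import multipletests

        pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        keep = []
        for cond, mat in (("A", a), ("B", b)):
            ps, rhos = [], []
            for i, j in pairs:
                r = stats.spearmanr(mat[:, i], mat[:, j])
                ps.append(r.pvalue); rhos.append(r.statistic)
            qs = multipletests(ps, method="fdr_bh")[1]
            keep.append({pairs[k] for k in range(len(pairs)) if abs(rhos[k]) > 0.8 and qs[k] <= 0.01})
        expect = keep[0] | keep[1]
        got = {(int(r["gene_x"][1:]), int(r["gene_y"][1:])) for _, r in cands.iterrows()}
        assert got == expect


class TestPermutationTest:
    def _planted_pairing(self, seed, n=20, rho=0.98):
        rng = np.random.default_rng(seed)
        f = rng.normal(size=n)
        a = np.column_stack([
            np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.normal(size=n),
            np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.normal(size=n),
            rng.normal(size=n),
        ])
        b = rng.normal(size=(n, 3))
        return _within_pairing(a, b)

    def test_seed_determinism(self):
        pairing = self._planted_pairing(1)
        cands = diffcorr.candidate_pairs(pairing)
        e1 = diffcorr.permutation_test(pairing, cands, n_perm=200, seed=7)
        e2 = diffcorr.permutation_test(pairing, cands, n_perm=200, seed=7)
        pd.testing.assert_frame_equal(e1, e2)

    def test_p_emp_lower_bound(self):
        pairing = self._planted_pairing(2)
        cands = diffcorr.candidate_pairs(pairing)
        edges = diffcorr.permutation_test(pairing, cands, n_perm=200, seed=0)
        assert (edges["p_emp"] >= 1 / 201 - 1e-12).all()

    def test_identical_conditions_give_large_p(self):
        rng = np.random.default_rng(3)
        n = 16
        f = rng.normal(size=n)
        a = np.column_stack([f + rng.normal(0, 0.2, n), f + rng.normal(0, 0.2, n)])
        pairing = _within_pairing(a, a.copy())  # same data in both conditions
        cands = diffcorr.candidate_pairs(pairing, rho_min=0.5, fdr=0.5)
        edges = diffcorr.permutation_test(pairing, cands, n_perm=300, seed=1)
        assert (edges["dz"].abs() < 1e-9).all()
        assert (edges["p_emp"] > 0.9).all()

    def test_dz_antisymmetric_under_condition_swap(self):
        pairing = self._planted_pairing(4)
        swapped = diffcorr.CompartmentPairing(
            "tumor-tumor", a_x=pairing.b_x, a_y=pairing.b_y, b_x=pairing.a_x, b_y=pairing.a_y
        )
        cands = diffcorr.candidate_pairs(pairing)
        e_fwd = diffcorr.permutation_test(pairing, cands, n_perm=100, seed=2)
        e_rev = diffcorr.permutation_test(swapped, cands, n_perm=100, seed=2)
        np.testing.assert_allclose(e_fwd["dz"].to_numpy(), -e_rev["dz"].to_numpy())

    def test_perfect_rho_clamped_finite(self):
        x = np.arange(12.0)
        a = np.column_stack([x, 2 * x + 1])
        pairing = _within_pairing(a, np.random.default_rng(5).normal(size=(12, 2)))
        cands = diffcorr.candidate_pairs(pairing, fdr=0.05)
        edges = diffcorr.permutation_test(pairing, cands, n_perm=100, seed=0)
        assert np.isfinite(edges["dz"]).all()


class TestSelectDifferential:
    def _edges(self, dz, q):
        return pd.DataFrame(
            {
                "gene_x": ["a"], "gene_y": ["b"], "rho_a": [0.9], "rho_b": [0.1],
                "z_a": [1.5], "z_b": [0.1], "dz": [dz], "p_emp": [q], "q": [q],
            }
        )

    def test_dz_one_point_three_nine_excluded(self):
        assert diffcorr.select_differential(self._edges(1.39, 0.001)).empty

    def test_dz_exactly_one_point_four_included(self):
        out = diffcorr.select_differential(self._edges(1.4, 0.001))
        assert len(out) == 1 and out["change"].iloc[0] == "gained"

    def test_matches_bruteforce_predicate(self):
        rng = np.random.default_rng(6)
        edges = pd.DataFrame(
            {
                "gene_x": [f"x{i}" for i in range(50)],
                "gene_y": [f"y{i}" for i in range(50)],
                "rho_a": rng.uniform(-1, 1, 50),
                "rho_b": rng.uniform(-1, 1, 50),
                "dz": rng.uniform(-3, 3, 50),
                "p_emp": rng.uniform(0, 0.05, 50),
                "q": rng.uniform(0, 0.05, 50),
            }
        )
        out = diffcorr.select_differential(edges)
        expect = {
            i for i in range(50)
            if edges["q"][i] <= 0.01 and abs(edges["dz"][i]) >= 1.4
        }
        assert set(out.index) == expect


class TestBuildNetwork:
    def _edge_frame(self, pairs):
        return pd.DataFrame(
            [
                {"gene_x": a, "gene_y": b, "rho_a": 0.9, "rho_b": 0.0, "dz": 1.5,
                 "q": 0.001, "change": "gained"}
                for a, b in pairs
            ]
        )

    def test_triangle_is_one_component_of_three(self):
        g, comps = diffcorr.build_network(
            self._edge_frame([("a", "b"), ("b", "c"), ("c", "a")]), "tumor", "tumor"
        )
        assert len(comps) == 1 and len(comps[0]) == 3

    def test_disjoint_pairs_all_size_two(self):
        g, comps = diffcorr.build_network(
            self._edge_frame([("a", "b"), ("c", "d"), ("e", "f")]), "tumor", "stroma"
        )
        assert [len(c) for c in comps] == [2, 2, 2]
        assert g.graph["size_class"]["pair"] == 3

    def test_components_match_unionfind_bruteforce(self):
        rng = np.random.default_rng(8)
        pairs = [(f"n{rng.integers(0, 15)}", f"n{rng.integers(0, 15)}") for _ in range(20)]
        pairs = [(a, b) for a, b in pairs if a != b]
        g, comps = diffcorr.build_network(self._edge_frame(pairs), "tumor", "tumor")
        # union-find over the same node universe
        parent = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in pairs:
            parent[find((a, "tumor"))] = find((b, "tumor"))
        groups = {}
        for node in parent:
            groups.setdefault(find(node), set()).add(node)
        assert sorted(map(len, comps), reverse=True) == sorted(map(len, groups.values()), reverse=True)

    def test_graphml_round_trip(self, tmp_path):
        g, _ = diffcorr.build_network(self._edge_frame([("a", "b"), ("b", "c")]), "tumor", "stroma")
        flat = nx.relabel_nodes(g, {n: f"{n[0]}|{n[1]}" for n in g.nodes})
        flat.graph.clear()
        path = tmp_path / "net.graphml"
        nx.write_graphml(flat, path, named_key_ids=True)
        back = nx.read_graphml(path)
        assert set(back.nodes) == {f"{n[0]}|{n[1]}" for n in g.nodes}
        assert back.number_of_edges() == g.number_of_edges()

    def test_annotations_applied(self):
        ann = diffcorr.NetworkAnnotation(
            tfs={"A"}, ligands={"b"}, receptors=set(),
            deg_status={"a": "up"}, known_interactions={frozenset({"A", "B"})},
        )
        g, _ = diffcorr.build_network(self._edge_frame([("a", "b")]), "tumor", "stroma", ann)
        assert g.nodes[("a", "tumor")]["is_tf"]
        assert g.nodes[("b", "stroma")]["is_ligand"]
        assert g.nodes[("a", "tumor")]["deg_status"] == "up"
        assert g.edges[("a", "tumor"), ("b", "stroma")]["known_interaction"]
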