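"""Association estimation, network inference algorithms, consensus, communities."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conet.inference import (
    ALGORITHMS,
    ESTIMATORS,
    AssociationMatrix,
    WeightedNetwork,
    association_matrix,
    consensus_network,
    detect_communities,
    discretize,
    infer_network,
)


class TestDiscretize:
    def test_default_bin_count_is_sqrt_n(self):
        x = np.arange(9, dtype=float).reshape(1, 9)
        d = discretize(x)  # ceil(sqrt(9)) = 3 bins
        assert set(d[0]) == {0, 1, 2}

    def test_equal_frequency_split(self):
        x = np.arange(1, 11, dtype=float).reshape(1, 10)
        d = discretize(x, n_bins=2)
        assert (d[0, :5] == 0).all() and (d[0, 5:] == 1).all()

    def test_ties_resolved_by_stable_order(self):
        # explicit quantile-assignment oracle: rank positions in stable
        # (original) order, then bin = position * B // n
        x = np.array([[2.0, 1.0, 2.0, 2.0, 3.0, 1.0]])
        d = discretize(x, n_bins=3)
        order = np.argsort(x[0], kind="stable")
        expected = np.empty(6, dtype=int)
        expected[order] = np.arange(6) * 3 // 6
        np.testing.assert_array_equal(d[0], expected)

    def test_constant_gene_single_bin(self):
        d = discretize(np.full((1, 8), 3.14), n_bins=3)
        assert (d == 0).all()

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.zeros((1, 5)), n_bins=1)


class TestAssociation:
    def test_perfect_linear_relation(self):
        x = np.vstack([np.arange(10.0), 2 * np.arange(10.0)])
        for est in ("pearson", "spearman", "kendall"):
            a = association_matrix(x, est)
            assert a.values[0, 1] == pytest.approx(1.0)

    def test_anticorrelation_stored_as_magnitude(self):
        x = np.vstack([np.arange(10.0), -np.arange(10.0)])
        a = association_matrix(x, "pearson")
        assert a.values[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("estimator", ESTIMATORS)
    def test_symmetry_and_zero_diagonal(self, estimator):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 20))
        a = association_matrix(x, estimator)
        np.testing.assert_allclose(a.values, a.values.T, atol=1e-12)
        assert (np.diag(a.values) == 0).all()
        if estimator in ("pearson", "spearman", "kendall"):
            assert (a.values <= 1 + 1e-12).all()
        assert (a.values >= 0).all()

    @pytest.mark.parametrize("estimator", ESTIMATORS)
    def test_constant_gene_zero_row(self, estimator):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(4, 15))
        x[2] = 7.0
        a = association_matrix(x, estimator)
        assert (a.values[2] == 0).all()

    def test_kendall_matches_scipy_pairwise(self):
        from scipy.stats import kendalltau

        rng = np.random.default_rng(7)
        x = rng.normal(size=(4, 12))
        x[1] = np.round(x[1], 0)  # introduce ties
        a = association_matrix(x, "kendall")
        for i, j in itertools.combinations(range(4), 2):
            tau = abs(kendalltau(x[i], x[j]).statistic)
            assert a.values[i, j] == pytest.approx(tau, abs=1e-12)

    def test_mi_matches_contingency_table_oracle(self):
        # fixed discrete pair, n=21, 3x3 joint table; hand enumeration of
        # H(X) + H(Y) - H(X,Y) and the Miller-Madow corrections
        x = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 0, 1, 2, 0, 1, 2, 0, 0, 1, 1, 2, 2])
        y = np.array([0, 0, 1, 1, 1, 2, 2, 2, 0, 0, 1, 2, 1, 2, 0, 0, 1, 1, 2, 2, 0])
        n = len(x)

        def plug_in_entropy(counts):
            p = np.asarray(counts, dtype=float) / n
            p = p[p > 0]
            return float(-(p * np.log(p)).sum())

        cx = [np.sum(x == v) for v in range(3)]
        cy = [np.sum(y == v) for v in range(3)]
        cxy = [np.sum((x == a) & (y == b)) for a in range(3) for b in range(3)]
        mi_emp = plug_in_entropy(cx) + plug_in_entropy(cy) - plug_in_entropy(cxy)
        occupied = sum(1 for c in cxy if c > 0)
        mi_mm = mi_emp + (3 - 1) / (2 * n) + (3 - 1) / (2 * n) - (occupied - 1) / (2 * n)

        data = np.vstack([x, y]).astype(float)
        a_emp = association_matrix(data, "mi_empirical", n_bins=3)
        a_mm = association_matrix(data, "mi_millermadow", n_bins=3)
        assert a_emp.values[0, 1] == pytest.approx(mi_emp, abs=1e-10)
        assert a_mm.values[0, 1] == pytest.approx(max(mi_mm, 0.0), abs=1e-10)

    def test_unknown_estimator_rejected(self):
        with pytest.raises(ValueError):
            association_matrix(np.zeros((2, 5)), "mutualinfo")


def _assoc(mat, genes=None):
    mat = np.asarray(mat, dtype=float)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    return AssociationMatrix(genes=genes, values=mat, estimator="pearson")


class TestInferNetwork:
    def test_aracne_prunes_weakest_triangle_edge(self):
        a = _assoc([[0, 0.9, 0.1], [0.9, 0, 0.8], [0.1, 0.8, 0]])
        net = infer_network(a, "aracne")
        assert net.weights[0, 2] == 0  # AC removed by DPI
        assert net.weights[0, 1] == pytest.approx(0.9)
        assert net.weights[1, 2] == pytest.approx(0.8)

    def test_aracne_eps_monotone(self):
        rng = np.random.default_rng(8)
        m = np.abs(rng.normal(size=(8, 8)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        a = _assoc(m)
        edges = [infer_network(a, "aracne", eps=e).n_edges for e in (0.0, 0.05, 0.2)]
        assert edges[0] <= edges[1] <= edges[2]

    def test_aracne_output_subset_of_input(self):
        rng = np.random.default_rng(9)
        m = np.abs(rng.normal(size=(6, 6)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        net = infer_network(_assoc(m), "aracne")
        assert ((net.weights > 0) <= (m > 0)).all()

    def test_clr_constant_matrix_gives_empty_network(self):
        a = _assoc(np.full((4, 4), 0.5) - 0.5 * np.eye(4))
        net = infer_network(a, "clr")
        assert net.n_edges == 0

    def test_clr_zscore_formula(self):
        m = np.array(
            [[0, 0.9, 0.1, 0.1], [0.9, 0, 0.1, 0.1], [0.1, 0.1, 0, 0.2], [0.1, 0.1, 0.2, 0]]
        )
        net = infer_network(_assoc(m), "clr")
        # direct recomputation of sqrt(max(0,zi)^2 + max(0,zj)^2)
        n = 4
        z = np.zeros((n, n))
        for i in range(n):
            row = np.delete(m[i], i)
            mu, sd = row.mean(), row.std()
            for j in range(n):
                if i != j:
                    z[i, j] = max(0.0, (m[i, j] - mu) / sd)
        expected = np.sqrt(z**2 + z.T**2)
        np.fill_diagonal(expected, 0)
        np.testing.assert_allclose(net.weights, expected, atol=1e-12)

    def test_mrnet_matches_greedy_mrmr_oracle(self):
        m = np.array(
            [
                [0, 0.8, 0.6, 0.1],
                [0.8, 0, 0.5, 0.3],
                [0.6, 0.5, 0, 0.4],
                [0.1, 0.3, 0.4, 0],
            ]
        )
        net = infer_network(_assoc(m), "mrnet")

        # independent forward-MRMR enumeration per target
        n = 4
        scores = np.full((n, n), -np.inf)
        for t in range(n):
            cand = [j for j in range(n) if j != t]
            selected = []
            while cand:
                best, best_s = None, -np.inf
                for j in cand:
                    red = np.mean([m[j, k] for k in selected]) if selected else 0.0
                    s = m[j, t] - red
                    if s > best_s:
                        best, best_s = j, s
                if best_s <= 0:
                    break
                scores[best, t] = best_s
                selected.append(best)
                cand.remove(best)
        expected = np.maximum(scores, scores.T)
        expected[expected < 0] = 0
        expected[~np.isfinite(expected)] = 0
        np.testing.assert_allclose(net.weights, expected, atol=1e-12)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            infer_network(_assoc(np.zeros((3, 3))), "wgcna")

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            AssociationMatrix(genes=["a", "b"], values=np.array([[0, 1], [2, 0]]),
                              estimator="pearson")


def _net(weights, genes=None):
    w = np.asarray(weights, dtype=float)
    genes = genes or [f"g{i}" for i in range(w.shape[0])]
    return WeightedNetwork(genes=genes, weights=w)


class TestConsensus:
    def test_identical_members_preserve_order(self):
        rng = np.random.default_rng(10)
        m = np.abs(rng.normal(size=(6, 6)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        single = _net(m)
        cons = consensus_network([single, single, single], density=0.4)
        el = cons.edge_list().sort_values("weight", ascending=False)
        ref = single.edge_list().sort_values("weight", ascending=False)
        kept = len(el)
        assert list(el[["gene_a", "gene_b"]].itertuples(index=False)) == list(
            ref.head(kept)[["gene_a", "gene_b"]].itertuples(index=False)
        )

    def test_edge_count_is_floor_of_density(self):
        rng = np.random.default_rng(11)
        nets = []
        for _ in range(3):
            m = np.abs(rng.normal(size=(15, 15)))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            nets.append(_net(m))
        cons = consensus_network(nets, density=0.1)
        assert cons.n_edges == math.floor(0.1 * 15 * 14 / 2)

    def test_mean_rank_arithmetic_oracle(self):
        # two members over 4 genes (6 pairs) with hand-computed Borda ranks
        m1 = np.array([[0, 6, 5, 4], [6, 0, 3, 2], [5, 3, 0, 1], [4, 2, 1, 0]], float)
        m2 = np.array([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]], float)
        cons = consensus_network([_net(m1), _net(m2)], density=1.0)
        # pair order (0,1),(0,2),(0,3),(1,2),(1,3),(2,3):
        # member1 ranks: 1,2,3,4,5,6 ; member2 ranks: 6,5,4,3,2,1 -> mean 3.5 all
        el = cons.edge_list()
        assert len(el) == 6
        assert el["weight"].nunique() == 1  # all pairs tie at mean rank 3.5

    def test_invariant_to_member_order(self):
        rng = np.random.default_rng(12)
        nets = []
        for _ in range(4):
            m = np.abs(rng.normal(size=(8, 8)))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            nets.append(_net(m))
        a = consensus_network(nets, density=0.3)
        b = consensus_network(nets[::-1], density=0.3)
        np.testing.assert_allclose(a.weights, b.weights)

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            consensus_network([], density=0.1)


def _clique_graph(cliques, extra_edges=()):
    nodes = sorted({v for c in cliques for v in c})
    genes = [f"g{v}" for v in nodes]
    idx = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for c in cliques:
        for a, b in itertools.combinations(c, 2):
            w[idx[a], idx[b]] = w[idx[b], idx[a]] = 1.0
    for a, b in extra_edges:
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = 1.0
    return WeightedNetwork(genes=genes, weights=w)


class TestCommunities:
    def test_two_cliques_joined_by_one_edge(self):
        net = _clique_graph([range(6), range(6, 12)], extra_edges=[(0, 6)])
        part = detect_communities(net, min_size=3)
        assert len(part.modules) == 2
        first = {g for g in part.assignments.index if part.assignments[g] == 1}
        assert first in ({f"g{i}" for i in range(6)}, {f"g{i}" for i in range(6, 12)})

    def test_ring_of_four_cliques(self):
        cliques = [range(8 * k, 8 * (k + 1)) for k in range(4)]
        ring = [(7, 8), (15, 16), (23, 24), (31, 0)]
        net = _clique_graph(cliques, extra_edges=ring)
        part = detect_communities(net)
        assert len(part.modules) == 4
        for c in cliques:
            labels = {part.assignments[f"g{v}"] for v in c}
            assert len(labels) == 1

    def test_edgeless_graph_gives_flagged_singletons(self):
        net = WeightedNetwork(genes=[f"g{i}" for i in range(5)], weights=np.zeros((5, 5)))
        part = detect_communities(net, min_size=10)
        assert len(part.modules) == 5
        assert part.excluded_modules == part.modules
        assert part.analysable_modules == []

    def test_partition_covers_nodes_exactly_once(self):
        net = _clique_graph([range(5), range(5, 9)], extra_edges=[(0, 5)])
        part = detect_communities(net)
        assert sorted(part.assignments.index) == sorted(net.genes)
        assert part.assignments.notna().all()


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_aracne_edges_never_exceed_input(seed):
    rng = np.random.default_rng(seed)
    m = np.abs(rng.normal(size=(7, 7)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    net = infer_network(_assoc(m), "aracne")
    assert ((net.weights > 0) <= (m > 0)).all()
    assert net.n_edges <= (m > 0).sum() // 2
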