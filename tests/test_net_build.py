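"""Network construction against naive loop oracles and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ktcspm import (
    adjacency,
    assemble_hetero,
    build_network,
    gip_kernel,
    logistic_transform,
    membership_matrix,
    weight_dd,
    weight_pd,
    weight_ppi,
)
from ktcspm.io_formats import DomainMap, PpiGraph

from .conftest import random_domain_map, random_graph

ATOL = 1e-12


# ---------------------------------------------------------------------------
# naive oracles
# ---------------------------------------------------------------------------


def naive_gip(adj, gamma_prime=1.0):
    n = adj.shape[0]
    gamma = gamma_prime / sum(np.dot(adj[k], adj[k]) for k in range(n))
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            diff = adj[i] - adj[j]
            out[i, j] = math.exp(-gamma * float(np.dot(diff, diff)))
    return out


def naive_wpp(lgks, graph: PpiGraph, sqrt_denom=False):
    n = graph.n_proteins
    nbrs = {p: graph.neighbors(p) for p in graph.proteins}
    out = np.zeros((n, n))
    for i, pi in enumerate(graph.proteins):
        for j, pj in enumerate(graph.proteins):
            if i == j:
                continue
            common = len(nbrs[pi] & nbrs[pj])
            denom = (len(nbrs[pi]) + 1) * (len(nbrs[pj]) + 1)
            if sqrt_denom:
                denom = math.sqrt(denom)
            out[i, j] = lgks[i, j] + common**2 / denom
    return out


def naive_wpd(w_pp, graph, dmap):
    out = np.zeros((graph.n_proteins, dmap.n_domains))
    for i, _p in enumerate(graph.proteins):
        for j, d in enumerate(dmap.domains):
            members = dmap.membership[d]
            out[i, j] = sum(w_pp[i, graph.index(k)] for k in members) / len(members)
    return out


def naive_wdd(w_pd, graph, dmap):
    nd = dmap.n_domains
    out = np.zeros((nd, nd))
    for i, di in enumerate(dmap.domains):
        for j, dj in enumerate(dmap.domains):
            a = sum(w_pd[graph.index(x), j] for x in dmap.membership[di])
            b = sum(w_pd[graph.index(y), i] for y in dmap.membership[dj])
            out[i, j] = (a + b) / (dmap.size(di) + dmap.size(dj))
    return out


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------


class TestAdjacency:
    def test_single_edge(self):
        g = PpiGraph(proteins=["A", "B"], edges={("A", "B")})
        assert adjacency(g).tolist() == [[0, 1], [1, 0]]

    def test_isolated_protein_row_zero(self):
        g = PpiGraph(proteins=["A", "B", "C"], edges={("A", "B")})
        assert adjacency(g)[2].sum() == 0

    def test_matches_edge_membership_oracle(self):
        g = random_graph(np.random.default_rng(0), 20)
        adj = adjacency(g)
        for i, pi in enumerate(g.proteins):
            for j, pj in enumerate(g.proteins):
                expected = float(frozenset((pi, pj)) in
                                 {frozenset(e) for e in g.edges})
                assert adj[i, j] == expected


# ---------------------------------------------------------------------------
# GIP kernel and logistic transform
# ---------------------------------------------------------------------------


class TestGipKernel:
    def test_two_node_closed_form(self):
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        gks = gip_kernel(adj)
        assert gks[0, 1] == pytest.approx(math.exp(-1.0), abs=1e-10)

    def test_diagonal_is_one(self):
        g = random_graph(np.random.default_rng(3), 10)
        gks = gip_kernel(adjacency(g))
        assert np.allclose(np.diag(gks), 1.0, atol=ATOL)

    def test_matches_naive_double_loop(self):
        g = random_graph(np.random.default_rng(5), 15)
        adj = adjacency(g)
        assert np.allclose(gip_kernel(adj, 1.7), naive_gip(adj, 1.7), atol=ATOL)

    def test_mean_norm_variant(self):
        g = random_graph(np.random.default_rng(6), 12)
        adj = adjacency(g)
        n = adj.shape[0]
        total = sum(np.dot(adj[k], adj[k]) for k in range(n))
        expected = naive_gip(adj, 1.0)  # recompute with mean-normalized gamma
        gamma = 1.0 / (total / n)
        for i in range(n):
            for j in range(n):
                diff = adj[i] - adj[j]
                expected[i, j] = math.exp(-gamma * float(np.dot(diff, diff)))
        assert np.allclose(gip_kernel(adj, mean_norm=True), expected, atol=ATOL)

    def test_all_zero_adjacency_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            gip_kernel(np.zeros((3, 3)))

    def test_nonpositive_gamma_prime_rejected(self):
        with pytest.raises(ValueError):
            gip_kernel(np.array([[0.0, 1.0], [1.0, 0.0]]), gamma_prime=0.0)


class TestLogisticTransform:
    @pytest.mark.parametrize("gks,expected", [
        (0.0, 1.0e-4),
        (1.0, 1.0 / (1.0 + 9999.0 * math.exp(-12.0))),
        (math.log(9999.0) / 12.0, 0.5),
    ])
    def test_closed_forms(self, gks, expected):
        assert logistic_transform(np.array(gks)) == pytest.approx(expected, abs=1e-10)

    def test_value_at_one_is_about_0_94212(self):
        assert logistic_transform(np.array(1.0)) == pytest.approx(0.94212, abs=5e-6)

    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_and_bounded(self, a, b):
        lo, hi = sorted((a, b))
        fa, fb = logistic_transform(np.array([lo, hi]))
        assert fa <= fb
        assert 1e-5 < fa and fb < 1.0


# ---------------------------------------------------------------------------
# weighting steps
# ---------------------------------------------------------------------------


class TestWeightPpi:
    def test_hand_example_overlap_term(self):
        # two proteins each of degree 3, sharing two neighbours, LGKS 0.5
        # -> 0.5 + 2^2 / (4*4) = 0.75
        g = PpiGraph(
            proteins=list("ABXYZW"),
            edges={("A", "X"), ("A", "Y"), ("A", "Z"),
                   ("B", "X"), ("B", "Y"), ("B", "W")},
        )
        adj = adjacency(g)
        lgks = np.full((6, 6), 0.5)
        w = weight_ppi(lgks, adj)
        assert w[0, 1] == pytest.approx(0.75, abs=ATOL)

    def test_no_common_neighbours_gives_lgks(self):
        g = PpiGraph(proteins=list("ABCD"), edges={("A", "B"), ("C", "D")})
        adj = adjacency(g)
        lgks = np.full((4, 4), 0.3)
        w = weight_ppi(lgks, adj)
        assert w[0, 2] == pytest.approx(0.3, abs=ATOL)

    @pytest.mark.parametrize("variant", ["plain", "sqrt"])
    def test_matches_naive_oracle(self, variant):
        g = random_graph(np.random.default_rng(8), 20)
        adj = adjacency(g)
        lgks = logistic_transform(gip_kernel(adj))
        w = weight_ppi(lgks, adj, overlap=variant)
        assert np.allclose(w, naive_wpp(lgks, g, sqrt_denom=(variant == "sqrt")),
                           atol=ATOL)

    def test_diagonal_zero_and_symmetric(self):
        g = random_graph(np.random.default_rng(9), 15)
        adj = adjacency(g)
        w = weight_ppi(logistic_transform(gip_kernel(adj)), adj)
        assert np.all(np.diag(w) == 0)
        assert np.allclose(w, w.T, atol=ATOL)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            weight_ppi(np.zeros((2, 2)), np.zeros((2, 2)), overlap="cube")


class TestWeightPdDd:
    @pytest.fixture()
    def fixture(self):
        rng = np.random.default_rng(10)
        g = random_graph(rng, 18)
        dmap = random_domain_map(rng, g, 6)
        adj = adjacency(g)
        w_pp = weight_ppi(logistic_transform(gip_kernel(adj)), adj)
        return g, dmap, w_pp

    def test_hand_example_membership_average(self):
        g = PpiGraph(proteins=["p", "a", "b"], edges={("p", "a"), ("p", "b")})
        dmap = DomainMap(domains=["dj"], membership={"dj": {"a", "b"}})
        w_pp = np.array([[0.0, 0.4, 0.6], [0.4, 0.0, 0.0], [0.6, 0.0, 0.0]])
        assert weight_pd(w_pp, dmap, g)[0, 0] == pytest.approx(0.5, abs=ATOL)

    def test_zero_weights_give_zero(self):
        g = PpiGraph(proteins=["p", "a"], edges=set())
        dmap = DomainMap(domains=["d"], membership={"d": {"a"}})
        assert weight_pd(np.zeros((2, 2)), dmap, g)[0, 0] == 0.0

    def test_wpd_matches_naive_oracle(self, fixture):
        g, dmap, w_pp = fixture
        assert np.allclose(weight_pd(w_pp, dmap, g), naive_wpd(w_pp, g, dmap),
                           atol=ATOL)

    def test_wdd_hand_example_singletons(self):
        g = PpiGraph(proteins=["x", "y"], edges={("x", "y")})
        dmap = DomainMap(domains=["di", "dj"],
                         membership={"di": {"x"}, "dj": {"y"}})
        w_pd = np.array([[0.0, 0.2], [0.4, 0.0]])
        w_dd = weight_dd(w_pd, dmap, g)
        assert w_dd[0, 1] == pytest.approx(0.3, abs=ATOL)

    def test_wdd_matches_naive_oracle_and_symmetric(self, fixture):
        g, dmap, w_pp = fixture
        w_pd = weight_pd(w_pp, dmap, g)
        w_dd = weight_dd(w_pd, dmap, g)
        assert np.allclose(w_dd, naive_wdd(w_pd, g, dmap), atol=ATOL)
        assert np.allclose(w_dd, w_dd.T, atol=ATOL)

    def test_all_zero_wpd_gives_zero_wdd(self):
        g = PpiGraph(proteins=["x", "y"], edges=set())
        dmap = DomainMap(domains=["d1", "d2"],
                         membership={"d1": {"x"}, "d2": {"y"}})
        assert np.all(weight_dd(np.zeros((2, 2)), dmap, g) == 0)


class TestAssembleHetero:
    def test_block_placement(self, small_bundle, small_het):
        het = small_het
        n_p = het.n_proteins
        assert np.array_equal(het.m_pd[:n_p, :n_p], het.w_pp)
        assert np.array_equal(het.m_pd[:n_p, n_p:], het.w_pd)
        assert np.array_equal(het.m_pd[n_p:, :n_p], het.w_pd.T)
        assert np.array_equal(het.m_pd[n_p:, n_p:], het.w_dd)

    def test_symmetric_and_nonnegative(self, small_het):
        m = small_het.m_pd
        assert np.linalg.norm(m - m.T) == pytest.approx(0.0, abs=1e-9)
        assert np.all(m >= 0)

    def test_dimension_mismatch_rejected(self):
        g = PpiGraph(proteins=["a", "b"], edges={("a", "b")})
        dmap = DomainMap(domains=["d"], membership={"d": {"a"}})
        with pytest.raises(ValueError, match="dimension"):
            assemble_hetero(np.zeros((3, 3)), np.zeros((2, 1)),
                            np.zeros((1, 1)), g, dmap)

    def test_three_node_shape(self):
        g = PpiGraph(proteins=["a", "b"], edges={("a", "b")})
        dmap = DomainMap(domains=["d"], membership={"d": {"a"}})
        het = build_network(g, dmap)
        assert het.m_pd.shape == (3, 3)
        assert het.node_ids == ["a", "b", "d"]


def test_adding_edge_never_decreases_common_neighbours():
    """Monotonicity of the shared-neighbour overlap under edge insertion."""
    rng = np.random.default_rng(11)
    g = random_graph(rng, 12, p=0.3)
    adj = adjacency(g)
    common_before = adj @ adj
    zero_pairs = [(i, j) for i in range(12) for j in range(i + 1, 12)
                  if adj[i, j] == 0]
    i, j = zero_pairs[0]
    adj2 = adj.copy()
    adj2[i, j] = adj2[j, i] = 1.0
    common_after = adj2 @ adj2
    assert np.all(common_after >= common_before)


def test_membership_matrix_matches_map(small_bundle):
    g, dmap = small_bundle["graph"], small_bundle["dmap"]
    m = membership_matrix(g, dmap)
    for d in dmap.domains:
        j = dmap.index(d)
        assert {g.proteins[i] for i in np.flatnonzero(m[:, j])} == dmap.membership[d]
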