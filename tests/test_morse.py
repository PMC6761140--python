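import math

import numpy as np
import pytest

import morseph as mp
from morseph.morse import MorseFunction
from .conftest import betti_rank_nullity


def injected_morse(cx, gvals, seed=0, order="lexicographic"):
    """Assign with hand-chosen vertex values (hand-trace scaffolding)."""
    return mp.assign_morse_function(cx, gvals, seed, order=order)


class TestVertexFunction:
    def test_single_vertex_in_noise_interval(self):
        g = mp.fixture_graph("single")
        vals = mp.vertex_function(g, 1)
        assert 0 < vals["a"] < 0.5

    def test_high_degree_vertex_gets_low_weight(self):
        # hub degree 5, pendant degree 1 in the 9-vertex fixture
        g = mp.fixture_graph("two_triangles")
        assert g.degree("v7") == 5 and g.degree("v8") == 1
        vals = mp.vertex_function(g, 3)
        assert 0 < vals["v7"] < 0.5
        assert 4 < vals["v8"] < 4.5
        assert vals["v8"] > vals["v7"]

    def test_regular_graph_all_in_noise_band(self):
        g = mp.fixture_graph("C4")  # 2-regular
        vals = mp.vertex_function(g, 5)
        assert all(0 < v < 0.5 for v in vals.values())

    def test_values_distinct_and_reproducible(self):
        g = mp.generate_er(60, 0.1, 2)
        v1 = mp.vertex_function(g, 9)
        v2 = mp.vertex_function(g, 9)
        assert v1 == v2
        assert len(set(v1.values())) == g.n_vertices


class TestAssignHandTraces:
    def test_single_vertex(self):
        g = mp.fixture_graph("single")
        cx = mp.build_clique_complex(g)
        f = injected_morse(cx, {"a": 0.25})
        assert f.values[0][0] == 0.25

    def test_p3_critical_is_the_hub_regardless_of_noise(self):
        # path a-b-c with low-weight middle vertex: both edges pair with
        # their pendant endpoint; only b survives as critical
        g = mp.fixture_graph("P3")
        cx = mp.build_clique_complex(g)
        for seed in range(5):
            f = injected_morse(cx, {"a": 1.2, "b": 0.3, "c": 1.4},
                               seed=seed, order="shuffled")
            ok, viol = mp.is_discrete_morse(cx, f)
            assert ok, viol
            crit = mp.find_critical(cx, f)
            assert crit.m_p == (1, 0)
            p, i = crit.critical[0]
            assert cx.simplices[p][i] == ("b",)

    def test_k3_lexicographic_trace(self):
        # g(a) < g(b) < g(c), edges processed lexicographically:
        # {a,b} pairs b; {a,c} pairs c; {b,c} falls back to f(c)+eps;
        # the triangle pairs with {b,c}; only the vertex a is critical
        g = mp.fixture_graph("K3")
        cx = mp.build_clique_complex(g)
        gv = {"a": 0.1, "b": 0.2, "c": 0.3}
        f = injected_morse(cx, gv, seed=4)
        e = {s: i for i, s in enumerate(cx.simplices[1])}
        assert f.values[1][e[("a", "b")]] == gv["b"]
        assert f.values[1][e[("a", "c")]] == gv["c"]
        assert f.values[1][e[("b", "c")]] > gv["c"]
        assert f.values[2][0] == f.values[1][e[("b", "c")]]
        crit = mp.find_critical(cx, f)
        assert crit.m_p == (1, 0, 0)
        assert cx.simplices[0][crit.critical[0][1]] == ("a",)

    def test_pairing_recorded_and_is_a_matching(self):
        g = mp.generate_er(30, 0.2, 8)
        cx = mp.build_clique_complex(g)
        f = mp.assign_morse_function(cx, mp.vertex_function(g, 1), 2)
        lowers = []
        for p in range(1, cx.dim + 1):
            for i, j in enumerate(f.pair_face[p]):
                if j >= 0:
                    # paired simplex takes exactly its max-facet value
                    assert f.values[p][i] == f.values[p - 1][int(j)]
                    lowers.append((p - 1, int(j)))
        # each face is claimed at most once, and the flags agree
        assert len(lowers) == len(set(lowers))
        for p in range(cx.dim):
            claimed = {j for q, j in lowers if q == p}
            assert claimed == set(np.flatnonzero(f.flag[p]).tolist())
        # no simplex is in two pairs (upper in one, lower in another)
        for p, j in lowers:
            assert f.pair_face[p][j] < 0

    def test_face_value_dominance(self):
        # f(alpha) >= every facet value, equality only in the pair branch
        g = mp.generate_ws(40, 4, 0.3, 3)
        cx = mp.build_clique_complex(g)
        f = mp.assign_morse_function(cx, mp.vertex_function(g, 5), 6)
        for p in range(1, cx.dim + 1):
            for i, fids in enumerate(cx.facets[p]):
                fmax = max(f.values[p - 1][j] for j in fids)
                if f.pair_face[p][i] >= 0:
                    assert f.values[p][i] == fmax
                else:
                    assert f.values[p][i] > fmax


class TestMorseProperty:
    def test_dimension_function_is_morse_everywhere(self):
        g = mp.generate_er(20, 0.4, 1)
        cx = mp.build_clique_complex(g)
        f = MorseFunction(
            [np.full(n, float(p)) for p, n in enumerate(cx.n_p)],
            [np.full(n, -1) for n in cx.n_p],
            [np.zeros(n, dtype=np.int8) for n in cx.n_p])
        ok, viol = mp.is_discrete_morse(cx, f)
        assert ok, viol
        # and every simplex is critical
        crit = mp.find_critical(cx, f)
        assert crit.m_p == cx.n_p

    def test_constant_function_on_k3_is_not_morse(self):
        cx = mp.build_clique_complex(mp.fixture_graph("K3"))
        f = MorseFunction(
            [np.zeros(n) for n in cx.n_p],
            [np.full(n, -1) for n in cx.n_p],
            [np.zeros(n, dtype=np.int8) for n in cx.n_p])
        ok, viol = mp.is_discrete_morse(cx, f)
        assert not ok
        assert any("|V|=2" in v for v in viol)

    def test_missing_values_rejected(self):
        cx = mp.build_clique_complex(mp.fixture_graph("K3"))
        with pytest.raises(ValueError):
            mp.is_discrete_morse(cx, MorseFunction([np.zeros(3)], [], []))

    @pytest.mark.parametrize("order", ["shuffled", "lexicographic"])
    def test_property_sweep_er_complexes(self, order):
        # the assignment yields a valid Morse function with exclusive
        # U/V sets on a sweep of seeded ER(50, 0.1) complexes
        for seed in range(25):
            g = mp.generate_er(50, 0.1, seed)
            cx = mp.build_clique_complex(g)
            f = mp.assign_morse_function(
                cx, mp.vertex_function(g, seed), seed + 1, order=order)
            ok, viol = mp.is_discrete_morse(cx, f)
            assert ok, viol
            # Forman exclusivity: U and V never both non-empty
            from morseph.morse import _uv_sizes
            assert all(u == 0 or v == 0
                       for _, _, u, v in _uv_sizes(cx, f.values))


class TestCriticalSet:
    def test_single_vertex_critical(self):
        g = mp.fixture_graph("single")
        cx = mp.build_clique_complex(g)
        f = injected_morse(cx, {"a": 0.4})
        crit = mp.find_critical(cx, f)
        assert crit.m_p == (1,) and crit.n_critical == 1

    def test_critical_weights_sorted_distinct(self):
        g = mp.generate_ba(60, 2, 3)
        cx = mp.build_clique_complex(g)
        f = mp.assign_morse_function(cx, mp.vertex_function(g, 2), 3)
        crit = mp.find_critical(cx, f)
        w = crit.critical_weights
        assert np.all(np.diff(w) > 0)
        assert set(w.tolist()) == {float(f.values[p][i])
                                   for p, i in crit.critical}


class TestMorseTheorems:
    def test_inequalities_and_euler_identity(self):
        # m_p >= beta_p and equal alternating sums, on every generator
        gens = [mp.generate_er(40, 0.12, 3), mp.generate_ws(40, 4, 0.5, 4),
                mp.generate_ba(40, 2, 5),
                mp.generate_hgg(40, 4.0, math.inf, 0.0, 6)]
        for g in gens:
            res = mp.analyze_graph(g, seed=9)
            beta = betti_rank_nullity(res.complex)
            assert all(m >= b for m, b in zip(res.m_p, beta))
            alt = lambda xs: sum((-1) ** p * x for p, x in enumerate(xs))
            assert alt(res.m_p) == alt(beta) == alt(res.n_p)


class TestOptimalityMu:
    def test_all_critical_gives_zero(self):
        assert mp.optimality_mu((5, 4), (5, 4), (1, 0)) == 0.0

    def test_attaining_lower_bound_gives_one(self):
        assert mp.optimality_mu((5, 4), (1, 2), (1, 2)) == 1.0

    def test_p3_hand_values(self):
        assert mp.optimality_mu((3, 2), (1, 0), (1, 0)) == 1.0

    def test_degenerate_single_vertex_convention(self):
        with pytest.warns(UserWarning):
            assert mp.optimality_mu((1,), (1,), (1,)) == 1.0

    def test_invalid_betti_exceeding_simplices(self):
        with pytest.raises(ValueError):
            mp.optimality_mu((2,), (2,), (5,))
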