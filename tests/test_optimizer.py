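"""SDA search behaviour: smell mechanics, walks, objective, full runs."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sdanet import (
    SDAParams,
    SmellState,
    choose_next,
    node_smell,
    objective,
    run_agent,
    run_sda,
    update_link_smell,
)
from sdanet.optimizer import _make_smell_state

from conftest import random_weighted_graph


def _line_graph(weights, edge_weights=None):
    g = nx.Graph()
    ids = [f"v{i}" for i in range(len(weights))]
    for n, w in zip(ids, weights):
        g.add_node(n, weight=float(w))
    for i in range(len(ids) - 1):
        ew = 1.0 if edge_weights is None else edge_weights[i]
        g.add_edge(ids[i], ids[i + 1], weight=float(ew))
    return g, ids


class TestNodeSmell:
    def test_zero_inputs_zero_smell(self):
        assert node_smell(0.0, 0.0, 0.7, 0.3) == 0.0

    def test_direct_combination(self):
        assert node_smell(1.0, 0.5, 0.5, 0.5) == pytest.approx(0.75)

    def test_coincides_with_integrated_node_weight(self, rng):
        # with matching coefficients, smell == the fused node weight
        g = nx.Graph()
        for i in range(5):
            gw, eig = float(rng.uniform(0, 2)), float(rng.uniform(0, 1))
            g.add_node(f"n{i}", g_w=gw, eigen=eig, weight=0.5 * gw + 0.5 * eig)
        g.add_edge("n0", "n1", weight=0.3)
        smell = _make_smell_state(g, 0.5, 0.5)
        for n, d in g.nodes(data=True):
            assert smell.node_smell[n] == pytest.approx(d["weight"])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            node_smell(float("nan"), 0.0, 0.5, 0.5)


class TestChooseNext:
    def test_all_neighbours_visited_returns_none(self):
        g, ids = _line_graph([1, 1, 1])
        smell = _make_smell_state(g, 0.5, 0.5)
        smell.visited.update(ids)
        assert choose_next(ids[1], smell, g) is None

    def test_strongest_link_smell_wins(self):
        g = nx.Graph()
        for n in "abc":
            g.add_node(n, weight=1.0)
        g.add_edge("a", "b", weight=0.9)
        g.add_edge("a", "c", weight=0.4)
        smell = _make_smell_state(g, 0.5, 0.5)
        assert choose_next("a", smell, g) == "b"

    def test_matches_exhaustive_argmax_on_random_states(self, rng):
        for _ in range(50):
            g = random_weighted_graph(rng, 10, p=0.5)
            smell = _make_smell_state(g, 0.5, 0.5)
            visited = {n for n in g.nodes if rng.random() < 0.3}
            smell.visited = set(visited)
            current = sorted(g.nodes)[int(rng.integers(10))]
            got = choose_next(current, smell, g)
            cands = [n for n in g.neighbors(current) if n not in visited]
            if not cands:
                assert got is None
                continue
            key = lambda n: (
                smell.link_smell[tuple(sorted((current, n)))],
                smell.node_smell[n],
                [-ord(c) for c in n],  # smaller id preferred on full tie
            )
            assert got == max(sorted(cands), key=key)

    def test_ties_break_by_node_smell_then_id(self):
        g = nx.Graph()
        g.add_node("a", weight=1.0)
        g.add_node("b", weight=0.2)
        g.add_node("c", weight=0.8)
        g.add_edge("a", "b", weight=0.5)
        g.add_edge("a", "c", weight=0.5)
        smell = _make_smell_state(g, 0.5, 0.5)
        assert choose_next("a", smell, g) == "c"  # equal link smell, higher node smell


class TestUpdateLinkSmell:
    def test_zero_delta_is_a_no_op(self):
        g, ids = _line_graph([1, 1])
        smell = _make_smell_state(g, 0.5, 0.5)
        before = dict(smell.link_smell)
        update_link_smell(smell, (ids[0], ids[1]), p=5.0, delta=0.0)
        assert smell.link_smell == before

    def test_direct_increment(self):
        g, ids = _line_graph([1, 1], edge_weights=[0.5])
        smell = _make_smell_state(g, 0.5, 0.5)
        update_link_smell(smell, (ids[0], ids[1]), p=1.0, delta=0.5)
        assert smell.link_smell[(ids[0], ids[1])] == pytest.approx(1.0)

    def test_update_sequence_is_order_independent_sum(self, rng):
        g, ids = _line_graph([1, 1, 1], edge_weights=[0.3, 0.7])
        e = (ids[0], ids[1])
        ps = rng.uniform(0, 3, size=12)
        for order in (ps, ps[::-1]):
            smell = _make_smell_state(g, 0.5, 0.5)
            for p in order:
                update_link_smell(smell, e, float(p), delta=0.5)
            assert smell.link_smell[e] == pytest.approx(0.3 + 0.5 * ps.sum())
            assert smell.link_smell[(ids[1], ids[2])] == 0.7

    def test_unknown_edge_rejected(self):
        g, ids = _line_graph([1, 1])
        smell = _make_smell_state(g, 0.5, 0.5)
        with pytest.raises(KeyError):
            update_link_smell(smell, ("x", "y"), 1.0, 0.5)


def _reference_walk(g, start, m, delta):
    """Independent step-by-step re-simulation of one agent's walk."""
    link = {tuple(sorted(e)): float(g.edges[e]["weight"]) for e in g.edges}
    nodew = {n: float(g.nodes[n]["weight"]) for n in g.nodes}
    visited = {start}
    path = [start]
    trail = [start]
    p = nodew[start]
    cur = start
    while len(path) < m:
        def options(node):
            return [nb for nb in sorted(g.neighbors(node)) if nb not in visited]

        opts = options(cur)
        if not opts:
            while trail and not options(trail[-1]):
                trail.pop()
            if not trail:
                break
            cur = trail[-1]
            continue
        nxt = max(opts, key=lambda nb: (link[tuple(sorted((cur, nb)))], nodew[nb],
                                        [-ord(c) for c in nb]))
        link[tuple(sorted((cur, nxt)))] += delta * p
        path.append(nxt)
        visited.add(nxt)
        p += nodew[nxt]
        trail.append(nxt)
        cur = nxt
    return path


class TestRunAgent:
    def test_module_size_one_returns_start(self):
        g, ids = _line_graph([1, 1, 1])
        smell = _make_smell_state(g, 0.5, 0.5)
        path = run_agent(ids[1], smell, g, SDAParams(module_size=1))
        assert path.nodes == [ids[1]]
        assert not path.terminated_early

    def test_path_graph_is_traversed_in_order(self):
        g, ids = _line_graph([1, 1, 1, 1, 1])
        smell = _make_smell_state(g, 0.5, 0.5)
        path = run_agent(ids[0], smell, g, SDAParams(module_size=5))
        assert path.nodes == ids

    def test_matches_independent_reference_simulation(self, rng):
        for trial in range(20):
            g = random_weighted_graph(rng, 15, p=0.25, min_component=6)
            comp = max(nx.connected_components(g), key=len)
            start = sorted(comp)[0]
            m = min(8, len(comp))
            params = SDAParams(module_size=m, delta=0.5)
            smell = _make_smell_state(g, 0.5, 0.5)
            got = run_agent(start, smell, g, params)
            assert got.nodes == _reference_walk(g, start, m, 0.5)

    def test_accumulated_weight_is_running_node_sum(self, rng):
        g = random_weighted_graph(rng, 12, p=0.5, min_component=8)
        smell = _make_smell_state(g, 0.5, 0.5)
        start = sorted(g.nodes)[0]
        path = run_agent(start, smell, g, SDAParams(module_size=6))
        sums = np.cumsum([g.nodes[n]["weight"] for n in path.nodes])
        assert np.allclose(path.accumulated, sums)

    def test_dead_end_sets_early_flag_on_exhausted_component(self):
        g, ids = _line_graph([1, 1, 1])
        smell = _make_smell_state(g, 0.5, 0.5)
        path = run_agent(ids[0], smell, g, SDAParams(module_size=10))
        assert path.terminated_early
        assert path.nodes == ids


class TestObjective:
    def test_singleton_scores_its_node_weight(self):
        g = nx.Graph()
        g.add_node("a", weight=1.7)
        assert objective(["a"], g) == pytest.approx(1.7)

    def test_uniform_triangle_scores_node_plus_edge_weight(self):
        g = nx.Graph()
        for n in "abc":
            g.add_node(n, weight=0.9)
        for u, v in (("a", "b"), ("b", "c"), ("a", "c")):
            g.add_edge(u, v, weight=0.4)
        assert objective(list("abc"), g) == pytest.approx(0.9 + 0.4)

    def test_matches_direct_summation_oracle(self, rng):
        g = random_weighted_graph(rng, 20, p=0.3)
        nodes = sorted(g.nodes)[:10]
        f = objective(nodes, g)
        sub = g.subgraph(nodes)
        expect = np.mean([g.nodes[n]["weight"] for n in nodes])
        if sub.number_of_edges():
            expect += np.mean([d["weight"] for *_, d in sub.edges(data=True)])
        assert f == pytest.approx(expect, abs=1e-12)

    def test_empty_set_rejected(self):
        g = nx.Graph()
        g.add_node("a", weight=1.0)
        with pytest.raises(ValueError):
            objective([], g)


class TestRunSDA:
    def test_clique_with_isolated_chaff_is_found(self, rng):
        g = nx.Graph()
        clique = [f"c{i}" for i in range(4)]
        for n in clique:
            g.add_node(n, weight=2.0)
        for i, u in enumerate(clique):
            for v in clique[i + 1:]:
                g.add_edge(u, v, weight=1.0)
        # low-weight pendant chain attached to the clique
        g.add_node("x0", weight=0.01)
        g.add_edge("c0", "x0", weight=0.01)
        res = run_sda(g, SDAParams(module_size=4, n_agents=1, restarts=1, seed=0,
                                   start_nodes=["c1"]))
        assert set(res.nodes) == set(clique)
        assert res.objective == pytest.approx(3.0)

    def test_byte_identical_determinism(self, rng):
        g = random_weighted_graph(rng, 40, p=0.15, min_component=12)
        params = SDAParams(module_size=8, seed=11, restarts=4)
        assert run_sda(g, params).to_json() == run_sda(g, params).to_json()

    def test_returned_objective_dominates_every_agent_path(self, rng):
        g = random_weighted_graph(rng, 30, p=0.2, min_component=10)
        res = run_sda(g, SDAParams(module_size=6, seed=3, restarts=5))
        for path in res.agent_paths:
            assert res.objective >= objective(path.nodes, g) - 1e-12

    def test_some_agent_reaches_full_module_size(self, rng):
        g = random_weighted_graph(rng, 30, p=0.2, min_component=12)
        res = run_sda(g, SDAParams(module_size=10, seed=3, restarts=3))
        assert max(len(p.nodes) for p in res.agent_paths) == 10
        assert len(res.nodes) <= 10

    def test_returned_module_is_connected(self, rng):
        g = random_weighted_graph(rng, 25, p=0.25, min_component=10)
        res = run_sda(g, SDAParams(module_size=7, seed=5, restarts=3))
        assert nx.is_connected(g.subgraph(res.nodes))

    def test_weight_scaling_scales_objective_not_selection(self, rng):
        g = random_weighted_graph(rng, 20, p=0.35, min_component=10)
        params = SDAParams(module_size=6, seed=9, restarts=3)
        res = run_sda(g, params)
        lam = 3.7
        g2 = g.copy()
        for n in g2.nodes:
            g2.nodes[n]["weight"] *= lam
        for u, v in g2.edges:
            g2.edges[u, v]["weight"] *= lam
        res2 = run_sda(g2, params)
        assert set(res2.nodes) == set(res.nodes)
        assert res2.objective == pytest.approx(lam * res.objective)

    def test_oversized_module_request_names_largest_component(self):
        g, _ = _line_graph([1, 1, 1])
        with pytest.raises(ValueError, match="largest component: 3"):
            run_sda(g, SDAParams(module_size=5))

    def test_agent_paths_are_node_disjoint(self, rng):
        g = random_weighted_graph(rng, 40, p=0.3, min_component=30)
        res = run_sda(g, SDAParams(module_size=5, n_agents=6, restarts=1, seed=2))
        seen = []
        for p in res.agent_paths:
            seen.extend(p.nodes)
        assert len(seen) == len(set(seen))


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 2**20), m=st.integers(2, 6))
def test_smell_reinforcement_never_decreases_link_smell(seed, m):
    """delta-increments only ever add: link smell >= initial edge weight."""
    r = np.random.default_rng(seed)
    g = random_weighted_graph(r, 14, p=0.4, min_component=m)
    smell = _make_smell_state(g, 0.5, 0.5)
    initial = dict(smell.link_smell)
    start = sorted(max(nx.connected_components(g), key=len))[0]
    run_agent(start, smell, g, SDAParams(module_size=m))
    for e, s in smell.link_smell.items():
        assert s >= initial[e] - 1e-15
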