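import networkx as nx
import numpy as np
import pytest

from modwalk.walktrap import (
    StopConfig,
    community_distance,
    delta_sigma,
    modularity,
    partition_summary,
    run_merge,
    select_partition,
    transition_model,
    vertex_distance,
)
from .conftest import random_connected_graph


# ---------------------------------------------------------------- oracles

def dense_walk_rows(g, t):
    """Explicit dense P^t via numpy matrix power — independent of the
    package's incremental construction."""
    nodes = sorted(g.nodes)
    A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    d = A.sum(axis=1)
    P = A / d[:, None]
    return nodes, np.linalg.matrix_power(P, t), d


def oracle_vertex_distance(g, t, i, j):
    nodes, Pt, d = dense_walk_rows(g, t)
    a, b = nodes.index(i), nodes.index(j)
    return np.sqrt(sum((Pt[a, k] - Pt[b, k]) ** 2 / d[k] for k in range(len(nodes))))


def oracle_community_row(g, t, comm):
    nodes, Pt, d = dense_walk_rows(g, t)
    idx = [nodes.index(v) for v in comm]
    return Pt[idx].mean(axis=0), d


def oracle_sigma(g, t, partition):
    """Mean squared vertex-to-community walk distance of a partition."""
    nodes, Pt, d = dense_walk_rows(g, t)
    n = len(nodes)
    total = 0.0
    for comm in partition:
        idx = [nodes.index(v) for v in comm]
        row = Pt[idx].mean(axis=0)
        for i in idx:
            total += np.sum((Pt[i] - row) ** 2 / d)
    return total / n


def oracle_modularity(g, partition, weighted=True):
    """Direct edge-counting modularity."""
    member = {v: k for k, comm in enumerate(partition) for v in comm}
    wts = {
        (u, v): (g.edges[u, v].get("weight", 1.0) if weighted else 1.0)
        for u, v in g.edges
    }
    total = sum(wts.values())
    q = 0.0
    for k, comm in enumerate(partition):
        inside = sum(w for (u, v), w in wts.items() if member[u] == k and member[v] == k)
        attached = sum(
            w * ((member[u] == k) + (member[v] == k)) for (u, v), w in wts.items()
        )
        q += inside / total - (attached / (2 * total)) ** 2
    return q


# ---------------------------------------------------------------- transition

class TestTransitionModel:
    def test_k3_one_step(self):
        m = transition_model(nx.complete_graph(3), t=1)
        for i in range(3):
            row = m.Pt[i]
            assert row[i] == 0.0
            assert sorted(row) == pytest.approx([0, 0.5, 0.5])

    def test_weighted_path_probabilities(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("b", "c", weight=3.0)
        m = transition_model(g, t=1)
        b, a, c = m.index("b"), m.index("a"), m.index("c")
        assert m.Pt[b, a] == pytest.approx(0.25)
        assert m.Pt[b, c] == pytest.approx(0.75)

    def test_k3_two_steps_hand_square(self):
        m = transition_model(nx.complete_graph(3), t=2)
        for i in range(3):
            for j in range(3):
                assert m.Pt[i, j] == pytest.approx(0.5 if i == j else 0.25)

    @pytest.mark.parametrize("t", [1, 3, 5])
    def test_rows_stochastic(self, rng, t):
        g = random_connected_graph(rng)
        m = transition_model(g, t=t)
        np.testing.assert_allclose(m.Pt.sum(axis=1), 1.0, atol=1e-9)

    def test_disconnected_rejected(self):
        g = nx.Graph([("A", "B"), ("X", "Y")])
        with pytest.raises(ValueError, match="connected"):
            transition_model(g)

    def test_self_loop_option_lazifies_walk(self):
        g = nx.path_graph(2)
        lazy = transition_model(g, t=1, self_loop_weight=1.0)
        assert lazy.Pt[0, 0] == pytest.approx(0.5)


# ---------------------------------------------------------------- distances

class TestDistances:
    def test_self_distance_zero(self, rng):
        g = random_connected_graph(rng)
        m = transition_model(g)
        for v in list(g.nodes)[:5]:
            assert vertex_distance(m, v, v) == 0.0

    def test_structurally_equivalent_leaves(self):
        g = nx.star_graph(4)  # hub 0, leaves 1..4
        m = transition_model(g)
        assert vertex_distance(m, 1, 2) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_vertex_distance_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(rng, n_max=6)
        m = transition_model(g)
        nodes = list(g.nodes)
        for i in nodes:
            for j in nodes:
                assert vertex_distance(m, i, j) == pytest.approx(
                    oracle_vertex_distance(g, 3, i, j), abs=1e-12
                )

    def test_singleton_community_distance_reduces_to_vertex(self, rng):
        g = random_connected_graph(rng, n_max=10)
        m = transition_model(g)
        u, v = list(g.nodes)[:2]
        assert community_distance(m, [u], [v]) == pytest.approx(
            vertex_distance(m, u, v)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_community_distance_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_connected_graph(rng, n_max=8)
        nodes = sorted(g.nodes)
        if len(nodes) < 5:
            pytest.skip("too small for 2+3 split")
        c1, c2 = nodes[:2], nodes[2:5]
        m = transition_model(g)
        row1, d = oracle_community_row(g, 3, c1)
        row2, _ = oracle_community_row(g, 3, c2)
        expected = np.sqrt(np.sum((row1 - row2) ** 2 / d))
        assert community_distance(m, c1, c2) == pytest.approx(expected, abs=1e-12)


class TestDeltaSigma:
    def test_two_singletons_closed_form(self, rng):
        g = random_connected_graph(rng, n_max=12)
        m = transition_model(g)
        u, v = next(iter(g.edges))
        r = vertex_distance(m, u, v)
        assert delta_sigma(m, [u], [v]) == pytest.approx(r**2 / (2 * m.n))

    def test_non_adjacent_pair_rejected(self):
        g = nx.path_graph(4)
        m = transition_model(g)
        with pytest.raises(ValueError, match="adjacent"):
            delta_sigma(m, [0], [3])

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_sigma_difference_along_full_merge(self, seed):
        """Merge cost must equal the brute-force increase in the mean
        squared vertex-to-community distance, at every step."""
        rng = np.random.default_rng(200 + seed)
        g = random_connected_graph(rng, n_max=20)
        hist = run_merge(g)
        comms = {i: {v} for i, v in enumerate(hist.nodes)}
        for rec in hist.records:
            before = oracle_sigma(g, 3, comms.values())
            comms[rec.new_id] = comms.pop(rec.merged_a) | comms.pop(rec.merged_b)
            after = oracle_sigma(g, 3, comms.values())
            assert rec.delta_sigma == pytest.approx(after - before, abs=1e-9)


class TestModularity:
    def test_single_community_is_zero(self, rng):
        g = random_connected_graph(rng, n_max=15)
        assert modularity(g, [set(g.nodes)]) == pytest.approx(0.0)

    def test_two_disconnected_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        q = modularity(g, [{0, 1, 2}, {3, 4, 5}], weighted=False)
        assert q == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_edge_counting_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        g = random_connected_graph(rng, n_max=20)
        nodes = list(g.nodes)
        k = int(rng.integers(2, 5))
        labels = rng.integers(0, k, size=len(nodes))
        partition = [
            {v for v, l in zip(nodes, labels) if l == c}
            for c in range(k)
            if np.any(labels == c)
        ]
        assert modularity(g, partition) == pytest.approx(
            oracle_modularity(g, partition), abs=1e-12
        )

    def test_rejects_non_partition(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            modularity(g, [{0, 1}])  # does not cover node 2

    def test_bounds_and_singleton_value(self, rng):
        g = random_connected_graph(rng, n_max=25)
        hist = run_merge(g)
        q = hist.q_sequence()
        assert np.all(q >= -1 - 1e-12) and np.all(q <= 1 + 1e-12)
        # singleton partition: e_C = 0, so Q = -sum a_C^2 <= 0
        w = {e: g.edges[e]["weight"] for e in g.edges}
        total = sum(w.values())
        deg = {v: 0.0 for v in g.nodes}
        for (u, v), wt in w.items():
            deg[u] += wt
            deg[v] += wt
        expected = -sum((dv / (2 * total)) ** 2 for dv in deg.values())
        assert hist.initial_Q == pytest.approx(expected)
        assert hist.initial_Q <= 0


# ---------------------------------------------------------------- merge run

def two_cliques_with_bridge(k=5):
    g = nx.disjoint_union(nx.complete_graph(k), nx.complete_graph(k))
    g.add_edge(0, k)
    return g


class TestRunMerge:
    def test_two_cliques_recovered_at_max_q(self):
        g = two_cliques_with_bridge()
        hist = run_merge(g)
        state = select_partition(hist, StopConfig(max_size=None))
        assert {frozenset(c) for c in state.communities} == {
            frozenset(range(5)),
            frozenset(range(5, 10)),
        }
        assert state.Q == pytest.approx(max(hist.q_sequence()))

    def test_connected_graph_has_n_minus_1_merges(self, rng):
        g = random_connected_graph(rng, n_max=25)
        hist = run_merge(g, stop=None)
        assert len(hist.records) == g.number_of_nodes() - 1
        assert len(hist.partition_at(len(hist.records))) == 1

    def test_max_size_nondecreasing(self, rng):
        g = random_connected_graph(rng, n_max=25)
        hist = run_merge(g)
        sizes = [r.max_size for r in hist.records]
        assert sizes == sorted(sizes)

    def test_relabeling_gives_isomorphic_history(self):
        rng = np.random.default_rng(7)
        g = random_connected_graph(rng, n_max=15)
        mapping = {v: f"N{v + 50}" for v in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        p1 = select_partition(run_merge(g), StopConfig(max_size=None))
        p2 = select_partition(run_merge(h), StopConfig(max_size=None))
        relabeled = {frozenset(mapping[v] for v in c) for c in p1.communities}
        assert relabeled == {frozenset(c) for c in p2.communities}

    def test_size_cap_halts_recording(self):
        g = two_cliques_with_bridge(6)
        hist = run_merge(g, stop=StopConfig(max_size=6))
        assert hist.records[-1].max_size > 6
        assert all(r.max_size <= 6 for r in hist.records[:-1])


class TestSelectPartition:
    def test_picks_max_q_step_under_cap(self, rng):
        g = random_connected_graph(rng, n_max=20)
        hist = run_merge(g, stop=None)
        # default selection track: topological modularity
        state = select_partition(hist, StopConfig(max_size=None))
        q_topo = hist.q_sequence(weighted=False)
        assert state.Q == pytest.approx(q_topo.max())
        assert q_topo[state.step] == pytest.approx(q_topo.max())
        # weighted track maximizes the walk-weight Q sequence instead
        state_w = select_partition(
            hist, StopConfig(max_size=None, modularity_on="walk_weights")
        )
        q_w = hist.q_sequence(weighted=True)
        assert state_w.Q == pytest.approx(q_w.max())

    def test_recorded_q_tracks_match_direct_modularity(self, rng):
        g = random_connected_graph(rng, n_max=15)
        hist = run_merge(g, stop=None)
        for step in (1, len(hist.records) // 2, len(hist.records)):
            part = hist.partition_at(step)
            assert hist.q_sequence()[step] == pytest.approx(
                modularity(g, part, weighted=True), abs=1e-9
            )
            assert hist.q_sequence(weighted=False)[step] == pytest.approx(
                modularity(g, part, weighted=False), abs=1e-9
            )

    def test_cap_excludes_oversized_steps(self):
        g = two_cliques_with_bridge(5)
        hist = run_merge(g, stop=None)
        state = select_partition(hist, StopConfig(max_size=4))
        assert max(len(c) for c in state.communities) <= 4

    def test_first_merge_over_cap_returns_singletons(self):
        g = nx.path_graph(5)
        hist = run_merge(g, stop=None)
        state = select_partition(hist, StopConfig(max_size=1))
        assert state.step == 0
        assert all(len(c) == 1 for c in state.communities)

    def test_score_criterion_uses_scorer(self):
        g = two_cliques_with_bridge(5)
        hist = run_merge(g, stop=None)
        # scorer preferring many communities drives selection to step 0
        state = select_partition(
            hist, StopConfig(max_size=None, criterion="score"), scorer=len
        )
        assert state.step == 0

    def test_score_without_scorer_errors(self):
        g = nx.path_graph(3)
        hist = run_merge(g)
        with pytest.raises(ValueError, match="scorer"):
            select_partition(hist, StopConfig(criterion="score"))


class TestPartitionSummary:
    def test_mixed_partition(self):
        parts = [{"1"}, {"2"}, {"a", "b"}, {"x", "y", "z"}, {"p", "q", "r", "s"}]
        s = partition_summary(parts)
        assert (s.singletons, s.pairs, s.triplets, s.modules) == (2, 1, 1, 1)
        assert s.max_module_size == 4
        assert s.n_communities == len(parts)

    def test_all_singletons(self):
        s = partition_summary([{i} for i in range(9)])
        assert (s.singletons, s.pairs, s.triplets, s.modules) == (9, 0, 0, 0)

    def test_cap_excludes_oversize_from_module_count(self):
        parts = [set(range(10)), set(range(10, 20)), set(range(20, 30)), {99}]
        s = partition_summary(parts, cap=10)
        assert s.modules == 3
        s2 = partition_summary(parts, cap=5)
        assert s2.modules == 0
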