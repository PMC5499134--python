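"""Evidence combination, STRING-file parsing, and the Steiner solver."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omicregnet.evidence import (
    DEFAULT_PRIOR,
    build_evidence_graph,
    combine_evidence,
    prior_correct,
    read_string_scores,
    solve_pcst,
    write_graphml,
    write_sif,
)


class TestPriorCorrection:
    def test_score_at_prior_cancels(self):
        assert prior_correct(DEFAULT_PRIOR) == 0.0

    def test_perfect_score_stays_one(self):
        assert prior_correct(1.0) == 1.0

    def test_hand_value(self):
        assert prior_correct(0.5, 0.063) == pytest.approx(0.46638, abs=1e-5)

    def test_below_prior_clamps_to_zero(self):
        assert prior_correct(0.01, 0.063) == 0.0

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_prior_rejected(self, p):
        with pytest.raises(ValueError):
            prior_correct(0.5, p)


class TestCombineEvidence:
    def test_single_channel_identity(self):
        for s in (0.1, 0.5, 0.8, 1.0):
            assert combine_evidence([s]) == pytest.approx(max(s, DEFAULT_PRIOR))

    def test_two_channel_hand_value(self):
        assert combine_evidence([0.5, 0.5], 0.063) == pytest.approx(0.7332, abs=1e-4)

    def test_floor_at_prior(self):
        assert combine_evidence([0.063, 0.063, 0.063], 0.063) == pytest.approx(0.063)

    def test_empty_channel_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            combine_evidence([])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        scores=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=5),
        extra=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_bounds_permutation_and_monotone_accumulation(self, scores, extra):
        s = combine_evidence(scores)
        assert DEFAULT_PRIOR - 1e-12 <= s <= 1.0 + 1e-12
        assert combine_evidence(scores[::-1]) == pytest.approx(s, abs=1e-12)
        assert combine_evidence(scores + [extra]) >= s - 1e-12
        assert s >= max(max(scores), DEFAULT_PRIOR) - 1e-12  # never below best channel


class TestStringFile:
    def test_integer_scale_autodetected(self, tmp_path):
        path = tmp_path / "links.txt"
        path.write_text(
            "protein1 protein2 experimental database combined_score\n"
            "gA gB 900 700 950\n"
            "gA gC 0 400 400\n"
            "gB gC 120 0 120\n"
        )
        df = read_string_scores(path)
        assert list(df.columns) == ["node_a", "node_b", "experimental", "database"]
        assert df.loc[0, "experimental"] == pytest.approx(0.9)
        assert df.loc[1, "database"] == pytest.approx(0.4)

    def test_fractional_scores_kept_as_is(self, tmp_path):
        path = tmp_path / "links.tsv"
        path.write_text("a\tb\texperimental\ng1\tg2\t0.25\n")
        df = read_string_scores(path)
        assert df.loc[0, "experimental"] == pytest.approx(0.25)


class TestEvidenceGraph:
    def _prizes(self):
        return pd.Series({"gA": 0.5, "gB": 0.4, "gC": 0.3})

    def test_channels_accumulate_above_best(self, tmp_path):
        string = pd.DataFrame(
            {"node_a": ["gA"], "node_b": ["gB"], "experimental": [0.9]}
        )
        G = build_evidence_graph(
            [("gA", "gB")], {("gA", "gB"): 0.7}, self._prizes(), string
        )
        assert G.edges["gA", "gB"]["score"] > 0.9
        assert G.edges["gA", "gB"]["cost"] == pytest.approx(
            1 - G.edges["gA", "gB"]["score"]
        )

    def test_local_only_edge_single_channel(self):
        G = build_evidence_graph([("gA", "gB")], {("gA", "gB"): -0.4}, self._prizes())
        assert G.edges["gA", "gB"]["score"] == pytest.approx(0.4)

    def test_missing_prize_rejected(self):
        with pytest.raises(ValueError, match="absent from prize"):
            build_evidence_graph(
                [("gA", "gZ")], {("gA", "gZ"): 0.5}, pd.Series({"gA": 0.1})
            )

    def test_trimmed_pairs_excluded(self):
        string = pd.DataFrame(
            {"node_a": ["gA", "gA"], "node_b": ["gB", "gC"],
             "experimental": [0.9, 0.9]}
        )
        G = build_evidence_graph(
            [("gA", "gB")], {("gA", "gB"): 0.5}, self._prizes(), string
        )
        assert not G.has_edge("gA", "gC")  # STRING evidence alone adds no edge


def brute_force_pcst(G: nx.Graph) -> float:
    """Exhaustive oracle: enumerate every edge subset whose induced graph is
    connected, plus all single nodes; return the minimal objective."""
    best = min(-G.nodes[v]["prize"] for v in G.nodes)
    edges = list(G.edges(data=True))
    for r in range(1, len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            H = nx.Graph()
            H.add_edges_from([(u, v) for u, v, _ in subset])
            if not nx.is_connected(H):
                continue
            obj = sum(d["cost"] for _, _, d in subset) - sum(
                G.nodes[v]["prize"] for v in H.nodes
            )
            best = min(best, obj)
    return best


class TestPcst:
    def test_cheap_edge_joins_two_good_nodes(self):
        G = nx.Graph()
        G.add_node(1, prize=1.0)
        G.add_node(2, prize=1.0)
        G.add_edge(1, 2, cost=0.1)
        sol = solve_pcst(G)
        assert set(sol.nodes) == {1, 2}
        assert sol.objective == pytest.approx(-1.9)

    def test_expensive_edge_leaves_weak_node_out(self):
        G = nx.Graph()
        G.add_node(1, prize=1.0)
        G.add_node(2, prize=0.05)
        G.add_edge(1, 2, cost=0.5)
        sol = solve_pcst(G)
        assert sol.nodes == [1]
        assert sol.objective == pytest.approx(-1.0)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        """20 seeded 8-node/12-edge instances: solver equals enumeration."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            G = nx.Graph()
            for v in range(8):
                G.add_node(v, prize=float(rng.uniform()))
            while G.number_of_edges() < 12:
                u, v = rng.integers(0, 8, size=2)
                if u != v:
                    G.add_edge(int(u), int(v), cost=float(rng.uniform()))
            sol = solve_pcst(G)
            assert sol.objective == pytest.approx(brute_force_pcst(G), abs=1e-9)

    def test_heuristic_respects_single_node_bound(self):
        # above the exact-size threshold the strong-pruning path still beats
        # the best single node
        rng = np.random.default_rng(77)
        G = nx.Graph()
        n = 25
        for v in range(n):
            G.add_node(v, prize=float(rng.uniform()))
        for _ in range(60):
            u, v = rng.integers(0, n, size=2)
            if u != v:
                G.add_edge(int(u), int(v), cost=float(rng.uniform()))
        sol = solve_pcst(G)
        assert sol.objective <= -max(G.nodes[v]["prize"] for v in G.nodes) + 1e-12
        sub = nx.Graph()
        sub.add_nodes_from(sol.nodes)
        sub.add_edges_from(sol.edges)
        assert nx.is_connected(sub)

    def test_heuristic_matches_exact_on_sparse_instances(self):
        # trees plus one chord: strong pruning is near-exact there; compare
        # against the exact enumerator run on the same graph
        from omicregnet.evidence import _solve_exact, _solve_heuristic

        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            G = nx.Graph()
            n = 9
            for v in range(n):
                G.add_node(v, prize=float(rng.uniform()))
            order = list(rng.permutation(n))
            for a, b in zip(order, order[1:]):  # random spanning tree
                G.add_edge(int(a), int(b), cost=float(rng.uniform()))
            exact = _solve_exact(G)
            heur = _solve_heuristic(G)
            assert heur.objective == pytest.approx(exact.objective, abs=1e-9)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            solve_pcst(nx.Graph())


class TestExports:
    def test_sif_and_graphml_round_out(self, tmp_path):
        G = nx.Graph()
        G.add_node("a", prize=0.3)
        G.add_node("b", prize=0.2)
        G.add_node("c", prize=0.1)
        G.add_edge("a", "b", cost=0.4, score=0.6)
        write_sif(G, tmp_path / "net.sif")
        lines = (tmp_path / "net.sif").read_text().strip().splitlines()
        assert lines[0] == "a\tpp\tb"
        assert "c" in lines[1]  # isolated node listed
        write_graphml(G, tmp_path / "net.graphml")
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.number_of_nodes() == 3
        assert back.nodes["a"]["prize"] == pytest.approx(0.3)
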