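"""DAG reasoning: d-separation and backdoor adjustment sets vs. oracles."""

import networkx as nx
import numpy as np
import pytest

import tripcausal as tc
from tripcausal.graph import AdjustmentSet, CausalDAG, IdentificationError

from oracles import (
    backdoor_sets_oracle,
    d_separated_oracle,
    random_dag,
)


def dag(edges, nodes=None):
    return CausalDAG.from_edges(edges, nodes=nodes)


class TestDSeparation:
    def test_chain_blocked_by_mediator(self):
        g = dag([("X", "M"), ("M", "Y")])
        assert tc.d_separated(g, "X", "Y", {"M"})
        assert not tc.d_separated(g, "X", "Y", set())

    def test_fork_blocked_by_common_cause(self):
        g = dag([("Z", "X"), ("Z", "Y")])
        assert not tc.d_separated(g, "X", "Y", set())
        assert tc.d_separated(g, "X", "Y", {"Z"})

    def test_collider_blocks_until_conditioned(self):
        g = dag([("X", "C"), ("Y", "C")])
        assert tc.d_separated(g, "X", "Y", set())
        assert not tc.d_separated(g, "X", "Y", {"C"})

    def test_collider_opened_by_descendant(self):
        g = dag([("X", "C"), ("Y", "C"), ("C", "D")])
        assert not tc.d_separated(g, "X", "Y", {"D"})

    def test_m_graph_opened_by_conditioning_on_m(self):
        g = dag([("U1", "X"), ("U1", "M"), ("U2", "M"), ("U2", "Y")])
        assert tc.d_separated(g, "X", "Y", set())
        assert not tc.d_separated(g, "X", "Y", {"M"})

    def test_unknown_labels_rejected(self):
        g = dag([("X", "Y")])
        with pytest.raises(KeyError):
            tc.d_separated(g, "X", "nope", set())

    def test_agreement_with_oracles_on_random_dags(self, rng):
        """Reachability vs. path enumeration vs. networkx on 30 random DAGs."""
        for _ in range(30):
            g = random_dag(5, 0.4, rng)
            G = CausalDAG(g)
            nodes = list(g.nodes)
            for x in nodes:
                for y in nodes:
                    if x == y:
                        continue
                    rest = [n for n in nodes if n not in (x, y)]
                    for bits in range(2 ** len(rest)):
                        Z = {rest[k] for k in range(len(rest)) if bits >> k & 1}
                        ours = tc.d_separated(G, x, y, Z)
                        assert ours == d_separated_oracle(g, x, y, Z)
                        assert ours == nx.is_d_separator(g, {x}, {y}, Z)


class TestBackdoorSets:
    def test_classic_confounder_needs_z(self):
        g = dag([("Z", "X"), ("Z", "Y"), ("X", "Y")])
        sets = tc.backdoor_sets(g, "X", "Y")
        assert [s.nodes for s in sets] == [frozenset({"Z"})]

    def test_unconfounded_edge_has_empty_minimal_set(self):
        g = dag([("X", "Y")])
        sets = tc.backdoor_sets(g, "X", "Y")
        assert sets[0].nodes == frozenset()
        assert sets[0].minimal

    def test_m_graph_empty_valid_but_m_invalid(self):
        g = dag([("U1", "X"), ("U1", "M"), ("U2", "M"), ("U2", "Y"), ("X", "Y")])
        valid = {s.nodes for s in tc.backdoor_sets(g, "X", "Y")}
        assert frozenset() in valid
        assert frozenset({"M"}) not in valid

    def test_descendants_of_source_never_adjusted(self):
        g = dag([("X", "D"), ("X", "Y"), ("D", "Y")])
        for s in tc.backdoor_sets(g, "X", "Y"):
            assert "D" not in s.nodes

    def test_sorted_by_size_then_lexicographic(self):
        g = dag([("A", "X"), ("A", "Y"), ("B", "X"), ("B", "Y"), ("X", "Y")])
        sets = tc.backdoor_sets(g, "X", "Y")
        sizes = [len(s.nodes) for s in sets]
        assert sizes == sorted(sizes)
        # both confounders are needed here
        assert sets[0].nodes == frozenset({"A", "B"})

    def test_max_size_truncates(self):
        g = dag([("A", "X"), ("A", "Y"), ("B", "X"), ("B", "Y"), ("X", "Y")])
        assert tc.backdoor_sets(g, "X", "Y", max_size=1) == []

    def test_oracle_equivalence_on_random_six_node_dags(self, rng):
        """Exhaustive subset enumeration agrees on 50 random 6-node DAGs."""
        for _ in range(50):
            g = random_dag(6, 0.35, rng)
            G = CausalDAG(g)
            nodes = list(g.nodes)
            for x in nodes[:3]:
                for y in nodes[3:]:
                    ours = {s.nodes for s in tc.backdoor_sets(G, x, y)}
                    oracle = set(backdoor_sets_oracle(g, x, y))
                    assert ours == oracle

    def test_every_returned_set_satisfies_type_invariants(self, rng):
        for _ in range(20):
            g = random_dag(6, 0.4, rng)
            G = CausalDAG(g)
            nodes = list(g.nodes)
            for x in nodes:
                for y in nodes:
                    if x == y:
                        continue
                    de_x = G.descendants(x)
                    for s in tc.backdoor_sets(G, x, y, max_size=2):
                        assert x not in s.nodes and y not in s.nodes
                        assert not (s.nodes & de_x)


class TestMinimalBackdoorSet:
    def test_confounder_graph(self):
        g = dag([("Z", "X"), ("Z", "Y"), ("X", "Y")])
        assert tc.minimal_backdoor_set(g, "X", "Y").nodes == {"Z"}

    def test_unconfounded_edge(self):
        g = dag([("X", "Y")])
        assert tc.minimal_backdoor_set(g, "X", "Y").nodes == frozenset()

    def test_lexicographic_tie_break(self):
        # either of the two confounders alone suffices (they are the same
        # variable duplicated through a chain); construct two singleton
        # valid sets {A} and {B} and expect {A}
        g = dag([("A", "B"), ("A", "X"), ("B", "Y"), ("X", "Y")])
        sets = tc.backdoor_sets(g, "X", "Y", max_size=1)
        assert {s.nodes for s in sets} == {frozenset({"A"}), frozenset({"B"})}
        assert tc.minimal_backdoor_set(g, "X", "Y").nodes == {"A"}

    def test_identification_failure_raised(self):
        # Y is a direct cause of X: the backdoor path X <- Y has no middle
        # node to block, so the effect of X on Y is not identifiable
        g = dag([("Y", "X")])
        with pytest.raises(IdentificationError):
            tc.minimal_backdoor_set(g, "X", "Y")
        assert tc.backdoor_sets(g, "X", "Y") == []

    def test_adjustment_set_rejects_source_or_target_member(self):
        with pytest.raises(ValueError):
            AdjustmentSet("x", "y", frozenset({"x"}))


class TestStudyGraph:
    def test_study_minimal_sets(self, table1_dag):
        assert tc.minimal_backdoor_set(
            table1_dag, "occupants", "before_valence"
        ).nodes == frozenset()
        assert tc.minimal_backdoor_set(
            table1_dag, "before_arousal", "after_arousal"
        ).nodes == {"sun"}
        assert tc.minimal_backdoor_set(
            table1_dag, "speed", "after_arousal"
        ).nodes == {"before_arousal"}

    def test_cycle_rejected_by_container(self):
        g = nx.DiGraph([("a", "b"), ("b", "a")])
        with pytest.raises(ValueError, match="cycle"):
            CausalDAG(g)

    def test_exports(self, table1_dag, tmp_path):
        table1_dag.to_edge_csv(tmp_path / "edges.csv")
        table1_dag.to_graphml(tmp_path / "dag.graphml")
        table1_dag.to_dot_file(tmp_path / "dag.dot")
        frame = table1_dag.to_edge_frame()
        assert len(frame) == 15
        back = nx.read_graphml(tmp_path / "dag.graphml")
        assert back.number_of_edges() == 15
        dot = (tmp_path / "dag.dot").read_text()
        assert '"occupants" -> "before_valence"' in dot

    def test_weight_matrix_round_trip(self, table1_spec, table1_dag):
        W = table1_dag.weight_matrix(table1_spec.nodes)
        np.testing.assert_allclose(W, table1_spec.weights)
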