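import itertools

import numpy as np
import pytest

from trireg.core import (
    EdgeConfidence,
    GeneRole,
    GlobalNetwork,
    TypedEdge,
)
from trireg.motifs import (
    enumerate_ffls,
    extract_interplay,
    motif_significance,
    randomize_network,
)


def brute_force_ffls(edges, roles, min_regulators=2):
    """Exhaustive scan over all ordered node triples."""
    pairs = {(e.source, e.target) for e in edges}
    nodes = sorted({n for e in edges for n in (e.source, e.target)})
    regs = {GeneRole.MIRNA, GeneRole.TF}
    found = []
    for a, b, c in itertools.permutations(nodes, 3):
        if (a, b) in pairs and (b, c) in pairs and (a, c) in pairs:
            if sum(roles[n] in regs for n in (a, b, c)) >= min_regulators:
                found.append((a, b, c))
    return sorted(found)


def _tf_edges(pairs):
    return frozenset(TypedEdge(a, b, "TF->TF") for a, b in pairs)


def _tf_roles(edges):
    return {n: GeneRole.TF for e in edges for n in (e.source, e.target)}


def _random_tf_graph(rng, n_nodes, p_edge):
    nodes = [f"tf{i:02d}" for i in range(n_nodes)]
    pairs = [
        (a, b)
        for a in nodes
        for b in nodes
        if a != b and rng.random() < p_edge
    ]
    edges = _tf_edges(pairs)
    roles = {n: GeneRole.TF for n in nodes}
    return edges, roles


class TestInterplay:
    def _network(self, confs, roles):
        return GlobalNetwork(roles, confs)

    def test_role_filter(self, roles_small):
        confs = [
            EdgeConfidence(TypedEdge("miR1", "tf1", "MIRNA->TF"), 60, 60, 1e-18),
            EdgeConfidence(TypedEdge("tf1", "miR2", "TF->MIRNA"), 60, 60, 1e-18),
            EdgeConfidence(TypedEdge("tf1", "geneA", "TF->MRNA"), 60, 60, 1e-18),
        ]
        net = self._network(confs, roles_small)
        inter = extract_interplay(net)
        assert {(e.source, e.target) for e in inter.edges} == {
            ("miR1", "tf1"),
            ("tf1", "miR2"),
        }
        # confidences preserved
        for e in inter.edges:
            assert inter.confidences[e] == net.confidences[e]

    def test_mrna_only_network_empty_interplay(self, roles_small):
        confs = [
            EdgeConfidence(TypedEdge("tf1", "geneA", "TF->MRNA"), 60, 60, 1e-18)
        ]
        assert len(extract_interplay(self._network(confs, roles_small))) == 0

    def test_idempotent(self, roles_small):
        confs = [
            EdgeConfidence(TypedEdge("miR1", "tf1", "MIRNA->TF"), 60, 60, 1e-18)
        ]
        net = self._network(confs, roles_small)
        once = extract_interplay(net)
        twice = extract_interplay(once)
        assert once.edges == twice.edges


class TestFFLEnumeration:
    def test_minimal_pattern(self):
        edges = _tf_edges([("A", "B"), ("B", "C"), ("A", "C")])
        out = enumerate_ffls((edges, _tf_roles(edges)))
        assert [(m.a, m.b, m.c) for m in out] == [("A", "B", "C")]
        assert out[0].regulator_count == 3

    def test_chain_is_not_a_loop(self):
        edges = _tf_edges([("A", "B"), ("B", "C")])
        assert enumerate_ffls((edges, _tf_roles(edges))) == []

    def test_regulator_filter_on_external_graph(self):
        # C is an mRNA here; with A,B regulators the FFL still qualifies
        roles = {"A": GeneRole.TF, "B": GeneRole.TF, "C": GeneRole.MRNA}
        edges = frozenset(
            [
                TypedEdge("A", "B", "TF->TF"),
                TypedEdge("B", "C", "TF->MRNA"),
                TypedEdge("A", "C", "TF->MRNA"),
            ]
        )
        assert len(enumerate_ffls((edges, roles))) == 1
        # raising the bar to 3 regulators removes it
        assert enumerate_ffls((edges, roles), min_regulators=3) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_triple_scan(self, seed):
        rng = np.random.default_rng(seed)
        edges, roles = _random_tf_graph(rng, 12, 0.2)
        got = [(m.a, m.b, m.c) for m in enumerate_ffls((edges, roles))]
        assert got == brute_force_ffls(edges, roles)


def _degree_census(edges):
    out_deg, in_deg = {}, {}
    for e in edges:
        out_deg[e.source] = out_deg.get(e.source, 0) + 1
        in_deg[e.target] = in_deg.get(e.target, 0) + 1
    return in_deg, out_deg


def _mutual_count(edges):
    pairs = {(e.source, e.target) for e in edges}
    return sum(1 for (a, b) in pairs if (b, a) in pairs) // 2


class TestRandomization:
    def test_single_edge_unchanged(self):
        edges = _tf_edges([("A", "B")])
        out, _ = randomize_network((edges, _tf_roles(edges)), swap_factor=5, seed=0)
        assert out == edges

    @pytest.mark.parametrize("seed", range(5))
    def test_preserves_degrees_mutual_dyads_and_types(self, seed):
        rng = np.random.default_rng(100 + seed)
        # mix of mutual and single edges
        pairs = [("A", "B"), ("B", "A"), ("C", "D"), ("D", "C"), ("E", "F"),
                 ("A", "C"), ("C", "E"), ("F", "B"), ("D", "F"), ("B", "E"),
                 ("E", "D"), ("F", "A"), ("A", "D")]
        edges = _tf_edges(pairs)
        roles = _tf_roles(edges)
        out, _ = randomize_network((edges, roles), swap_factor=10, seed=seed)
        assert _degree_census(out) == _degree_census(edges)
        assert _mutual_count(out) == _mutual_count(edges)
        assert len(out) == len(edges)
        for e in out:
            assert e.source != e.target
            assert e.edge_type in ("TF->TF",)

    def test_respects_role_feasibility(self, roles_small):
        # miR->tf and tf->mRNA singles: a naive swap would propose
        # miR->mRNA (fine) and tf->tf, but never mRNA sources
        edges = frozenset(
            [
                TypedEdge("miR1", "tf1", "MIRNA->TF"),
                TypedEdge("tf2", "geneA", "TF->MRNA"),
                TypedEdge("miR2", "geneB", "MIRNA->MRNA"),
            ]
        )
        out, _ = randomize_network((edges, roles_small), swap_factor=20, seed=3)
        for e in out:
            assert roles_small[e.source] is not GeneRole.MRNA

    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        edges, roles = _random_tf_graph(rng, 10, 0.25)
        a, _ = randomize_network((edges, roles), swap_factor=10, seed=5)
        b, _ = randomize_network((edges, roles), swap_factor=10, seed=5)
        assert a == b


class TestSignificance:
    def test_zero_real_count_p_is_one(self):
        edges = _tf_edges([("A", "B"), ("B", "C")])
        report = motif_significance((edges, _tf_roles(edges)), n_random=20, seed=0)
        assert report.real_count == 0
        assert report.empirical_p == 1.0

    def test_degenerate_null_no_z(self):
        # a single edge cannot be rewired: every null equals the real count
        edges = _tf_edges([("A", "B")])
        report = motif_significance((edges, _tf_roles(edges)), n_random=10, seed=0)
        assert report.z_score is None
        assert report.empirical_p == 1.0

    def test_planted_ffls_significant(self):
        # 12 planted FFLs over a sparse background
        pairs = []
        for i in range(12):
            a, b, c = f"a{i}", f"b{i}", f"c{i}"
            pairs += [(a, b), (b, c), (a, c)]
        pairs += [(f"c{i}", f"a{(i+1) % 12}") for i in range(12)]
        edges = _tf_edges(pairs)
        report = motif_significance(
            (edges, _tf_roles(edges)), n_random=100, swap_factor=10, seed=1
        )
        assert report.real_count == 12
        assert report.empirical_p <= 0.05
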