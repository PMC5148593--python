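"""Shell layers: BFS distances, Venn associations, side-chain constraint."""

import networkx as nx
import numpy as np
import pytest

from shellmap.contacts import build_contact_network
from shellmap.layers import (
    FunctionalRegion,
    assign_layers,
    region_association,
    sidechain_constrained_association,
    steps_to_regions,
)
from shellmap.structure import ResidueID, select_residues
from shellmap.synth import make_shell_cluster

from conftest import graph_as_network, make_residue


def rid(n: int) -> ResidueID:
    return ResidueID("A", n)


def region(name: str, *numbers: int) -> FunctionalRegion:
    return FunctionalRegion(name=name, members=frozenset(rid(n) for n in numbers))


class TestStepsToRegions:
    def test_path_graph_distances(self):
        net = graph_as_network(nx.path_graph([1, 2, 3]))
        table = steps_to_regions(net, [region("GBS", 1)])
        assert [table[rid(n)].steps_to_region["GBS"] for n in (1, 2, 3)] == [0, 1, 2]
        assert [table[rid(n)].layer for n in (1, 2, 3)] == [0, 1, 2]

    def test_two_regions_tie_on_path(self):
        net = graph_as_network(nx.path_graph([1, 2, 3]))
        table = steps_to_regions(net, [region("GBS", 1), region("ABS", 3)])
        mid = table[rid(2)]
        assert mid.steps_to_region == {"GBS": 1, "ABS": 1}
        assert region_association(mid) == frozenset({"GBS", "ABS"})

    def test_missing_member_warns_and_is_listed(self):
        net = graph_as_network(nx.path_graph([1, 2, 3]))
        with pytest.warns(UserWarning, match="A:99"):
            table = steps_to_regions(net, [region("GBS", 1, 99)])
        assert table.missing_members["GBS"] == [rid(99)]

    def test_empty_network_errors(self):
        from shellmap.contacts import ContactNetwork
        empty = ContactNetwork(cutoff=5.0, scope="intra_chain", nodes=set(), edges={})
        with pytest.raises(ValueError):
            steps_to_regions(empty, [region("GBS", 1)])

    def test_overlapping_regions_rejected(self):
        net = graph_as_network(nx.path_graph([1, 2, 3]))
        with pytest.raises(ValueError, match="disjoint"):
            steps_to_regions(net, [region("GBS", 1), region("ABS", 1)])

    @pytest.mark.parametrize("seed", range(10))
    def test_distances_match_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        graph = nx.gnp_random_graph(25, 0.12, seed=seed)
        net = graph_as_network(graph)
        members = rng.choice(25, size=3, replace=False)
        regions = [region("GBS", *(int(m) + 0 for m in members[:2])),
                   region("CR", int(members[2]))]
        table = steps_to_regions(net, regions)
        # independent oracle: Floyd-Warshall all-pairs minima over member sets
        apsp = nx.floyd_warshall(graph)
        for node in graph.nodes:
            for reg, member_idx in (("GBS", members[:2]), ("CR", members[2:])):
                oracle = min(apsp[int(m)][node] for m in member_idx)
                got = table[rid(node)].steps_to_region.get(reg)
                if oracle == float("inf"):
                    assert got is None
                else:
                    assert got == int(oracle)


class TestAssignLayers:
    def test_partition_exhaustive_and_disjoint(self):
        graph = nx.gnp_random_graph(30, 0.1, seed=5)
        net = graph_as_network(graph)
        table = steps_to_regions(net, [region("GBS", 0, 1)])
        parts = assign_layers(table)
        all_ids = [x for part in parts.values() for x in part]
        assert sorted(all_ids) == sorted(net.nodes)
        assert len(all_ids) == len(set(all_ids))

    def test_functional_residue_is_layer_zero(self):
        net = graph_as_network(nx.path_graph([1, 2, 3]))
        table = steps_to_regions(net, [region("GBS", 1)])
        parts = assign_layers(table)
        assert parts["L0"] == [rid(1)]
        assert parts["L1"] == [rid(2)]
        assert parts["L2"] == [rid(3)]

    def test_deeper_shells_labelled_beyond(self):
        net = graph_as_network(nx.path_graph(range(1, 6)))
        table = steps_to_regions(net, [region("GBS", 1)])
        parts = assign_layers(table, max_layer=2)
        assert parts["beyond"] == [rid(4), rid(5)]

    def test_densification_never_increases_steps(self):
        base = nx.path_graph(range(8))
        denser = base.copy()
        denser.add_edge(0, 5)
        regions = [region("GBS", 0)]
        t1 = steps_to_regions(graph_as_network(base), regions)
        t2 = steps_to_regions(graph_as_network(denser), regions)
        for n in base.nodes:
            assert (t2[rid(n)].steps_to_region["GBS"]
                    <= t1[rid(n)].steps_to_region["GBS"])


class TestShellClusterRecovery:
    @pytest.mark.parametrize("seed", range(8))
    def test_pipeline_recovers_generated_truth(self, seed):
        st, truth = make_shell_cluster([1, 2], [3, 4], seed=seed)
        net = build_contact_network(select_residues(st, "A"))
        table = steps_to_regions(net, truth.regions)
        for res_id, layer in truth.layer.items():
            assert table[res_id].layer == layer
            assert table[res_id].association == truth.association[res_id]

    def test_degenerate_single_residue(self):
        st, truth = make_shell_cluster([1], [], seed=0)
        assert truth.layer == {rid(1): 0}
        assert truth.association[rid(1)] == frozenset({"GBS"})


class TestSidechainConstraint:
    def _fixture(self):
        """Query residue: side chain points at region A's shell, backbone at B's."""
        ra = make_residue("A", 1, [("CA", (0.0, 0, 0))])       # region A member
        mid1 = make_residue("A", 2, [("CA", (4.0, 0, 0))])     # L1 of A
        query = make_residue(
            "A", 3,
            [("N", (9.2, 0, 0)), ("CA", (9.6, 0, 0)), ("C", (10.0, 0, 0)),
             ("O", (10.4, 0, 0)), ("CB", (6.0, 1.0, 0))],
            name="LYS",
        )
        mid2 = make_residue("A", 4, [("CA", (12.0, 0, 0))])    # L1 of B
        rb = make_residue("A", 5, [("CA", (16.0, 0, 0))])      # region B member
        residues = [ra, mid1, query, mid2, rb]
        net = build_contact_network(residues)
        regions = [region("GBS", 1), region("ABS", 5)]
        return net, regions, query.id

    def test_unconstrained_is_tied_but_constraint_picks_side_chain_route(self):
        net, regions, q = self._fixture()
        table = steps_to_regions(net, regions)
        assert region_association(table[q]) == frozenset({"GBS", "ABS"})
        constrained = sidechain_constrained_association(net, regions, q, table=table)
        assert constrained == frozenset({"GBS"})

    def test_enumerated_paths_agree_with_constraint(self):
        net, regions, q = self._fixture()
        graph = net.to_graph()
        # first edge must carry the query's side-chain flag
        allowed_first = [
            nbr for nbr in graph.neighbors(q)
            if (net.contact(q, nbr).a_side_chain_involved
                if net.contact(q, nbr).res_a == q
                else net.contact(q, nbr).b_side_chain_involved)
        ]
        best: dict[str, int] = {}
        for reg in regions:
            lengths = []
            for nbr in allowed_first:
                for member in reg.members:
                    try:
                        lengths.append(
                            1 + nx.shortest_path_length(graph, nbr, member)
                        )
                    except nx.NetworkXNoPath:
                        pass
            if lengths:
                best[reg.name] = min(lengths)
        minimum = min(best.values())
        expected = frozenset(n for n, v in best.items() if v == minimum)
        got = sidechain_constrained_association(net, regions, q)
        assert got == expected

    def test_glycine_query_is_empty_with_warning(self):
        gly = make_residue(
            "A", 3, [("N", (8.0, 0, 0)), ("CA", (9.0, 0, 0)), ("C", (10.0, 0, 0)),
                     ("O", (11.0, 0, 0))], name="GLY",
        )
        ra = make_residue("A", 1, [("CA", (5.0, 0, 0))])
        rb = make_residue("A", 2, [("CA", (13.0, 0, 0))])
        net = build_contact_network([ra, gly, rb])
        regions = [region("GBS", 1)]
        with pytest.warns(UserWarning, match="no side-chain"):
            got = sidechain_constrained_association(net, regions, gly.id)
        assert got == frozenset()

    def test_functional_residue_returns_its_own_region(self):
        net, regions, _ = self._fixture()
        got = sidechain_constrained_association(net, regions, rid(1))
        assert got == frozenset({"GBS"})
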