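"""Plant-drug network construction and component detection."""

import numpy as np
import pytest

from phytoscreen import PlantDrugNetwork, build_network, connected_components
from phytoscreen.io_chem import CompoundRecord, DrugPanel, PlantRecord


def _plant(pid, cids, name=None):
    return PlantRecord(
        plant_id=pid, plant_name=name or pid, family="F", compound_ids=set(cids)
    )


def _panel(stage, drugs):
    return DrugPanel(stage=stage, drugs=[CompoundRecord(i, s) for i, s in drugs])


STEROID = "CC12CCC3C(CCC4CC(O)CCC34C)C1CCC2O"


class TestBuildNetwork:
    def test_identical_compound_gives_edge_with_unit_evidence(self):
        library = [CompoundRecord("c1", STEROID)]
        plants = [_plant("p1", ["c1"])]
        panels = [_panel("approved", [("d1", STEROID)])]
        net = build_network(plants, panels, library)
        assert net.n_edges == 1
        assert net.graph.edges["p1", "d1"]["evidence"] == [("c1", 1.0)]

    def test_two_compounds_one_drug_single_edge_two_evidence(self):
        library = [
            CompoundRecord("c1", STEROID),
            CompoundRecord("c2", "C" + STEROID),
        ]
        plants = [_plant("p1", ["c1", "c2"])]
        panels = [_panel("approved", [("d1", STEROID)])]
        net = build_network(plants, panels, library)
        assert net.n_edges == 1
        assert len(net.graph.edges["p1", "d1"]["evidence"]) == 2

    def test_empty_plant_list_warns_empty_network(self, caplog):
        with caplog.at_level("WARNING"):
            net = build_network([], [_panel("approved", [("d1", "CCO")])], [])
        assert net.n_edges == 0 and not list(net.graph.nodes)

    def test_most_advanced_stage_labels_shared_drug(self):
        library = [CompoundRecord("c1", STEROID)]
        plants = [_plant("p1", ["c1"])]
        panels = [
            _panel("preclinical", [("d1", STEROID)]),
            _panel("approved", [("d1", STEROID)]),
        ]
        net = build_network(plants, panels, library)
        assert net.graph.nodes["d1"]["stage"] == "approved"

    def test_edge_set_invariant_to_compound_order(self):
        library = [
            CompoundRecord("c1", STEROID),
            CompoundRecord("c2", "CC" + STEROID),
            CompoundRecord("c3", "CCO"),
        ]
        panels = [_panel("approved", [("d1", STEROID)])]
        a = build_network([_plant("p1", ["c1", "c2", "c3"])], panels, library)
        b = build_network([_plant("p1", ["c3", "c2", "c1"])], panels, library[::-1])
        assert sorted(a.graph.edges()) == sorted(b.graph.edges())

    def test_subset_of_plants_never_adds_edges(self, dataset, calls, acea_results):
        sig = {r.plant_id for r in acea_results if r.significant}
        sig_plants = [p for p in dataset.plants if p.plant_id in sig]
        full = build_network(sig_plants, dataset.panels, dataset.compounds, calls=calls)
        half = build_network(
            sig_plants[: len(sig_plants) // 2], dataset.panels, dataset.compounds,
            calls=calls,
        )
        assert set(half.graph.edges()) <= set(full.graph.edges())


class TestConnectedComponents:
    def _net_from_edges(self, edges, isolated=()):
        net = PlantDrugNetwork()
        for p, d in edges:
            net.graph.add_node(p, node_type="plant")
            net.graph.add_node(d, node_type="drug")
            net.graph.add_edge(p, d, evidence=[("c", 1.0)])
        for node in isolated:
            net.graph.add_node(node, node_type="plant")
        return net

    def test_single_edge_single_component(self):
        comps = connected_components(self._net_from_edges([("A", "D")]))
        assert comps == [["A", "D"]]

    def test_disjoint_edges_two_components(self):
        comps = connected_components(
            self._net_from_edges([("A", "D1"), ("B", "D2")])
        )
        assert len(comps) == 2

    def test_empty_network_zero_components(self):
        assert connected_components(PlantDrugNetwork()) == []

    def test_isolated_nodes_form_no_component(self):
        comps = connected_components(
            self._net_from_edges([("A", "D")], isolated=["L"])
        )
        assert comps == [["A", "D"]]

    def test_sorted_by_size_then_smallest_member(self):
        comps = connected_components(
            self._net_from_edges([("B", "D2"), ("A", "D1"), ("C", "D3"), ("C", "D4")])
        )
        assert comps[0] == ["C", "D3", "D4"]
        assert comps[1:] == [["A", "D1"], ["B", "D2"]]

    def test_matches_union_find_oracle_on_random_graphs(self):
        # independent oracle: textbook union-find over the same random edges
        rng = np.random.default_rng(0)
        for _ in range(25):
            n_p, n_d = rng.integers(2, 12, size=2)
            plants = [f"p{i}" for i in range(n_p)]
            drugs = [f"d{i}" for i in range(n_d)]
            edges = [
                (plants[rng.integers(n_p)], drugs[rng.integers(n_d)])
                for _ in range(rng.integers(1, 20))
            ]
            parent = {x: x for x in plants + drugs}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for a, b in edges:
                parent[find(a)] = find(b)
            touched = {x for e in edges for x in e}
            expected = len({find(x) for x in touched})
            net = self._net_from_edges(set(edges))
            assert len(connected_components(net)) == expected
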