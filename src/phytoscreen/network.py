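"""Bipartite plant-drug network over significantly enriched plants.

A plant connects to a drug when at least one compound of the plant has MACCS
Tanimoto similarity >= 0.70 to the drug; each edge stores its evidence pairs
(compound_id, Tc). By default all annotated compounds of a plant can create
edges; ``actives_only=True`` restricts edge evidence to predicted actives. A
drug listed at several development stages is labelled by the most advanced one
(approved > clinical > preclinical).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .chem_core import fingerprint_matrix
from .errors import StructureError
from .io_chem import CompoundRecord, DrugPanel, PlantRecord
from .similarity import DEFAULT_TC_THRESHOLD

logger = logging.getLogger(__name__)

_STAGE_RANK = {"preclinical": 0, "clinical": 1, "approved": 2}


@dataclass
class PlantDrugNetwork:
    """Undirected bipartite graph with plant and drug node attributes."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def plant_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["node_type"] == "plant"
        )

    @property
    def drug_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["node_type"] == "drug"
        )

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    significant_plants: list[PlantRecord],
    panels: list[DrugPanel],
    library: list[CompoundRecord],
    calls=None,
    threshold: float = DEFAULT_TC_THRESHOLD,
    actives_only: bool = False,
) -> PlantDrugNetwork:
    """Connect enriched plants to drugs via compound-level similarity.

    Only plants passed in (normally the ACEA-significant ones) become plant
    nodes; only drugs with at least one above-threshold compound become drug
    nodes. Node degree is stored as an attribute for downstream rendering.
    """
    net = PlantDrugNetwork()
    if not significant_plants:
        logger.warning("no significant plants; returning empty network")
        return net

    active_ids = (
        {c.compound_id for c in calls if c.is_active} if calls is not None else None
    )

    # drug table with most-advanced-stage labelling
    drug_stage: dict[str, str] = {}
    drug_smiles: dict[str, str] = {}
    for panel in sorted(panels, key=lambda p: _STAGE_RANK[p.stage]):
        for drug in panel.drugs:
            drug_stage[drug.compound_id] = panel.stage  # later (more advanced) wins
            drug_smiles[drug.compound_id] = drug.smiles
    drug_ids = sorted(drug_stage)

    lib_by_id = {c.compound_id: c for c in library}
    # compounds eligible to carry evidence, deduplicated across plants
    eligible: set[str] = set()
    for plant in significant_plants:
        for cid in plant.compound_ids:
            if cid not in lib_by_id:
                continue
            if active_ids is not None and actives_only and cid not in active_ids:
                continue
            eligible.add(cid)
    comp_ids = sorted(eligible)

    comp_fps, kept_comp_ids = [], []
    for cid in comp_ids:
        try:
            comp_fps.append(fingerprint_matrix([lib_by_id[cid].smiles]))
            kept_comp_ids.append(cid)
        except StructureError:
            logger.warning("skipping unparseable compound %s in network stage", cid)
    import numpy as np

    C = np.vstack(comp_fps) if comp_fps else np.zeros((0, 166), bool)
    D = fingerprint_matrix([drug_smiles[d] for d in drug_ids])

    from .chem_core import tanimoto_matrix

    T = tanimoto_matrix(C, D) if C.size and D.size else np.zeros((len(kept_comp_ids), len(drug_ids)))

    comp_index = {cid: i for i, cid in enumerate(kept_comp_ids)}
    for plant in sorted(significant_plants, key=lambda p: p.plant_id):
        net.graph.add_node(
            plant.plant_id, node_type="plant", family=plant.family,
            plant_name=plant.plant_name,
        )
        for cid in sorted(plant.compound_ids):
            i = comp_index.get(cid)
            if i is None:
                continue
            for j in np.flatnonzero(T[i] >= threshold):
                did = drug_ids[j]
                if did not in net.graph:
                    net.graph.add_node(did, node_type="drug", stage=drug_stage[did])
                if not net.graph.has_edge(plant.plant_id, did):
                    net.graph.add_edge(plant.plant_id, did, evidence=[])
                net.graph.edges[plant.plant_id, did]["evidence"].append(
                    (cid, float(T[i, j]))
                )
    for node in net.graph.nodes:
        net.graph.nodes[node]["degree"] = net.graph.degree(node)
    logger.info(
        "network: %d plants, %d drugs, %d edges",
        len(net.plant_nodes), len(net.drug_nodes), net.n_edges,
    )
    return net


def connected_components(network: PlantDrugNetwork) -> list[list[str]]:
    """Components over plant+drug nodes, each sorted lexicographically;
    components ordered by size descending, then by smallest member.

    Isolated (degree-0) nodes form no component: plants that passed enrichment
    but resemble no drug are reported in the node table, not as sub-networks.
    """
    comps = [
        sorted(c)
        for c in nx.connected_components(network.graph)
        if not (len(c) == 1 and network.graph.degree(next(iter(c))) == 0)
    ]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps
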