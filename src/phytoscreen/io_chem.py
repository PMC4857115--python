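"""Readers and writers for every external representation the pipeline touches:
SMILES / SDF structure files, TSV annotation and result tables, and
Cytoscape-loadable network exports (SIF + GraphML).

Conventions: all tables are UTF-8 TSV with a header row; floats are written
with 12 significant digits so write→read round-trips reproduce values; invalid
structures are skipped with a logged reason, never fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
from rdkit import Chem

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

STAGES = ("preclinical", "clinical", "approved")

#: float format used by every table writer; 12 significant digits guarantee
#: value-faithful round-trips at double precision for the quantities we emit.
FLOAT_FORMAT = "%.12g"


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule of the library or of a drug panel."""

    compound_id: str
    smiles: str
    name: str | None = None


@dataclass
class PlantRecord:
    """One plant with its annotated compound ids."""

    plant_id: str
    plant_name: str
    family: str
    compound_ids: set[str] = field(default_factory=set)

    @property
    def m(self) -> int:
        return len(self.compound_ids)


@dataclass
class DrugPanel:
    """Drugs at one development stage (preclinical / clinical / approved)."""

    stage: str
    drugs: list[CompoundRecord]

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ConfigurationError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}"
            )
        ids = [d.compound_id for d in self.drugs]
        if len(ids) != len(set(ids)):
            raise ConfigurationError(f"duplicate drug ids in {self.stage} panel")


def _parseable(smiles: str) -> bool:
    return Chem.MolFromSmiles(smiles) is not None


def read_smiles_file(path) -> list[CompoundRecord]:
    """Read a .smi file of whitespace-separated ``SMILES id [name...]`` lines.

    Unparseable structures are dropped and counted in the log.
    """
    records: list[CompoundRecord] = []
    n_bad = 0
    seen: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        parts = line.split()
        if not parts:
            continue
        smiles = parts[0]
        cid = parts[1] if len(parts) > 1 else f"line{len(records) + n_bad + 1}"
        name = " ".join(parts[2:]) or None
        if cid in seen:
            logger.warning("duplicate compound id %s skipped", cid)
            continue
        if not _parseable(smiles):
            n_bad += 1
            logger.warning("unparseable SMILES for %s skipped: %s", cid, smiles)
            continue
        seen.add(cid)
        records.append(CompoundRecord(compound_id=cid, smiles=smiles, name=name))
    if n_bad:
        logger.info("dropped %d unparseable structures from %s", n_bad, path)
    return records


def read_sdf(path) -> list[CompoundRecord]:
    """Read a V2000 SDF; record id from the molecule title (_Name)."""
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    supplier = Chem.SDMolSupplier(str(path))
    n_bad = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            n_bad += 1
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i + 1}"
        if cid in seen:
            logger.warning("duplicate compound id %s skipped", cid)
            continue
        seen.add(cid)
        records.append(CompoundRecord(compound_id=cid, smiles=Chem.MolToSmiles(mol)))
    if n_bad:
        logger.info("dropped %d unreadable SDF records from %s", n_bad, path)
    return records


def read_structures(path) -> list[CompoundRecord]:
    path = Path(path)
    if path.suffix.lower() in (".sdf", ".sd", ".mol"):
        return read_sdf(path)
    return read_smiles_file(path)


REQUIRED_ANNOTATION_COLUMNS = ("compound_id", "plant_id", "plant_name", "family")


def read_compound_library(structures_path, annotation_path):
    """Read a compound library and its plant annotation.

    Returns ``(compounds, plants)`` sorted by id. Compounds referenced by the
    annotation but absent from the structure file are dropped and counted in
    the log; a compound may belong to several plants but appears once in the
    library.
    """
    compounds = read_structures(structures_path)
    if not compounds:
        raise InputError(f"empty compound library in {structures_path}")
    by_id = {c.compound_id: c for c in compounds}

    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    for col in REQUIRED_ANNOTATION_COLUMNS:
        if col not in ann.columns:
            raise ConfigurationError(
                f"annotation table {annotation_path} lacks required column {col!r}"
            )

    plants: dict[str, PlantRecord] = {}
    n_skipped = 0
    for row in ann.itertuples(index=False):
        if row.compound_id not in by_id:
            n_skipped += 1
            continue
        plant = plants.setdefault(
            row.plant_id,
            PlantRecord(
                plant_id=row.plant_id, plant_name=row.plant_name, family=row.family
            ),
        )
        plant.compound_ids.add(row.compound_id)
    if n_skipped:
        logger.info(
            "skipped %d annotation rows referencing unknown compounds", n_skipped
        )
    compounds_sorted = sorted(by_id.values(), key=lambda c: c.compound_id)
    plants_sorted = sorted(plants.values(), key=lambda p: p.plant_id)
    return compounds_sorted, plants_sorted


def read_drug_panels(path) -> list[DrugPanel]:
    """Read a TSV with columns drug_id, smiles, stage into per-stage panels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("drug_id", "smiles", "stage"):
        if col not in df.columns:
            raise ConfigurationError(f"panel table {path} lacks required column {col!r}")
    panels = []
    for stage in STAGES:
        sub = df[df["stage"] == stage]
        drugs = []
        for row in sub.itertuples(index=False):
            if not _parseable(row.smiles):
                logger.warning("unparseable drug %s skipped", row.drug_id)
                continue
            drugs.append(CompoundRecord(compound_id=row.drug_id, smiles=row.smiles))
        if drugs:
            panels.append(DrugPanel(stage=stage, drugs=sorted(drugs, key=lambda d: d.compound_id)))
    if not panels:
        raise InputError(f"no usable drugs in {path}")
    return panels


def write_smiles_file(records, path) -> None:
    lines = [
        f"{r.smiles}\t{r.compound_id}" + (f"\t{r.name}" if r.name else "")
        for r in records
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_network(network, out_prefix) -> list[Path]:
    """Write a plant-drug network as ``<prefix>.sif`` and ``<prefix>.graphml``.

    Both files are bit-stable: nodes and edges are emitted in sorted order, so
    writing the same network twice yields byte-identical files. An empty
    network still produces a valid (edge-free) pair of files with a warning.
    """
    out_prefix = Path(out_prefix)
    sif_path = out_prefix.with_suffix(".sif")
    graphml_path = out_prefix.with_suffix(".graphml")

    edges = sorted((p, d) for p, d in network.graph.edges())
    if not edges:
        logger.warning("writing empty network to %s", out_prefix)
    sif_lines = [f"{p}\tsimilar_to\t{d}" for p, d in edges]
    sif_path.write_text("\n".join(sif_lines) + ("\n" if sif_lines else ""), encoding="utf-8")

    # rebuild in sorted order so GraphML serialization is deterministic
    g = nx.Graph()
    for node in sorted(network.graph.nodes()):
        data = network.graph.nodes[node]
        attrs = {
            "node_type": data.get("node_type", ""),
            "degree": int(network.graph.degree(node)),
        }
        if data.get("node_type") == "plant":
            attrs["family"] = data.get("family", "")
        else:
            attrs["stage"] = data.get("stage", "")
        g.add_node(node, **attrs)
    for p, d in edges:
        g.add_edge(p, d, n_evidence=len(network.graph.edges[p, d].get("evidence", [])))
    nx.write_graphml(g, graphml_path)
    return [sif_path, graphml_path]
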