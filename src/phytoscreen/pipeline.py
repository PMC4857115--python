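"""End-to-end orchestration: activity screen → plant enrichment → drug
similarity → property/fragment characterization → plant-drug network.

Every stage writes a flat TSV (or SIF/GraphML for the network) into the run's
output directory, and a ``summary.json`` records the stage counts plus the
output manifest. Runs are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .activity import fit_activity_model, predict_library
from .chem_core import (
    compute_fingerprint,
    compute_properties,
    fingerprint_matrix,
    lipinski_flags,
)
from .enrichment import run_acea
from .errors import ConfigurationError, PhytoscreenError, StructureError
from .fragments import FragmentDictionary, frequency_table
from .io_chem import (
    read_compound_library,
    read_drug_panels,
    read_smiles_file,
    write_network,
    write_table,
)
from .network import build_network, connected_components
from .similarity import stage_report
from .synthetic import GeneratorConfig, generate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and thresholds of one pipeline run.

    Either ``synthetic`` carries a GeneratorConfig, or all four input paths
    (library/annotation/panels/reference sets) must be set.
    """

    outdir: str = "phytoscreen_run"
    seed: int = 0
    synthetic: GeneratorConfig | None = None
    library_path: str | None = None
    annotation_path: str | None = None
    panels_path: str | None = None
    reference_actives_path: str | None = None
    reference_decoys_path: str | None = None
    alpha_activity: float = 0.05
    alpha_adj: float = 0.05
    tc_threshold: float = 0.70
    network_actives_only: bool = False
    fragment_dictionary_path: str | None = None

    def validate(self) -> None:
        for name in ("alpha_activity", "alpha_adj", "tc_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.synthetic is None:
            required = (
                "library_path", "annotation_path", "panels_path",
                "reference_actives_path", "reference_decoys_path",
            )
            missing = [n for n in required if getattr(self, n) is None]
            if missing:
                raise ConfigurationError(
                    f"non-synthetic run needs paths for: {', '.join(missing)}"
                )
            for n in required:
                p = Path(getattr(self, n))
                if not p.exists():
                    raise ConfigurationError(f"{n} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if isinstance(syn, dict):
                if "compounds_per_plant" in syn:
                    syn["compounds_per_plant"] = tuple(syn["compounds_per_plant"])
                cfg.synthetic = GeneratorConfig(**syn)
            elif syn:
                cfg.synthetic = GeneratorConfig(seed=cfg.seed)
        return cfg


@dataclass
class RunSummary:
    n_compounds: int = 0
    n_plants: int = 0
    n_active: int = 0
    active_percent: int = 0
    n_significant_plants: int = 0
    similarity: dict = field(default_factory=dict)  # stage -> {n_similar, percent}
    n_network_plants: int = 0
    n_network_drugs: int = 0
    n_network_edges: int = 0
    n_components: int = 0
    outputs: list[str] = field(default_factory=list)
    seed: int = 0
    version: str = __version__

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.__dict__, indent=2, sort_keys=True), encoding="utf-8"
        )


def _load_inputs(config: RunConfig, outdir: Path):
    if config.synthetic is not None:
        gen = config.synthetic
        gen.seed = config.seed
        dataset = generate_dataset(gen)
        write_dataset(dataset, outdir / "inputs")
        return (
            dataset.compounds,
            dataset.plants,
            dataset.panels,
            dataset.reference_actives,
            dataset.reference_decoys,
        )
    compounds, plants = read_compound_library(
        config.library_path, config.annotation_path
    )
    panels = read_drug_panels(config.panels_path)
    ref_actives = read_smiles_file(config.reference_actives_path)
    ref_decoys = read_smiles_file(config.reference_decoys_path)
    return compounds, plants, panels, ref_actives, ref_decoys


def _fps_of(records):
    kept, fps = [], []
    for r in records:
        try:
            fps.append(compute_fingerprint(r.smiles).bits)
        except StructureError:
            logger.warning("skipping unparseable structure %s", r.compound_id)
            continue
        kept.append(r)
    import numpy as np

    return kept, (np.vstack(fps) if fps else np.zeros((0, 166), bool))


def _property_table(records, label: str) -> pd.DataFrame:
    rows = []
    for r in records:
        try:
            p = compute_properties(r.smiles)
        except StructureError:
            continue
        flags = lipinski_flags(p)
        rows.append(
            {
                "compound_id": r.compound_id,
                "set": label,
                "alogp": p.alogp,
                "mol_weight": p.mol_weight,
                "hbd": p.hbd,
                "hba": p.hba,
                "rotatable_bonds": p.rotatable_bonds,
                "n_rings": p.n_rings,
                "n_aromatic_rings": p.n_aromatic_rings,
                "lipinski_hbd_ok": flags.hbd_ok,
                "lipinski_hba_ok": flags.hba_ok,
                "lipinski_mw_ok": flags.mw_ok,
                "lipinski_alogp_ok": flags.alogp_ok,
                "lipinski_pass": flags.passes,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute all stages; any stage error aborts with the stage named."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "pipeline start %s | seed=%d | phytoscreen %s",
        datetime.now(timezone.utc).isoformat(timespec="seconds"),
        config.seed, __version__,
    )
    summary = RunSummary(seed=config.seed)
    stage = "load_inputs"
    try:
        compounds, plants, panels, ref_actives, ref_decoys = _load_inputs(
            config, outdir
        )
        summary.n_compounds = len(compounds)
        summary.n_plants = len(plants)

        stage = "activity"
        _, ra_fps = _fps_of(ref_actives)
        _, rd_fps = _fps_of(ref_decoys)
        model = fit_activity_model(ra_fps, rd_fps)
        calls = predict_library(model, compounds, alpha=config.alpha_activity)
        calls_df = pd.DataFrame(
            [
                {
                    "compound_id": c.compound_id,
                    "score": c.score,
                    "p_value": c.p_value,
                    "is_active": c.is_active,
                }
                for c in calls
            ]
        )
        write_table(calls_df, outdir / "activity_calls.tsv")
        summary.n_active = int(sum(c.is_active for c in calls))
        from .similarity import round_percent

        summary.active_percent = round_percent(summary.n_active, len(calls))

        stage = "enrichment"
        results = run_acea(plants, calls, alpha_adj=config.alpha_adj)
        enr_df = pd.DataFrame(
            [
                {
                    "plant_id": r.plant_id,
                    "plant_name": r.plant_name,
                    "family": r.family,
                    "N": r.N, "n": r.n, "m": r.m, "k": r.k,
                    "p": r.p, "p_adj": r.p_adj,
                    "significant": r.significant,
                }
                for r in results
            ]
        )
        write_table(enr_df, outdir / "enrichment.tsv")
        summary.n_significant_plants = int(sum(r.significant for r in results))

        stage = "similarity"
        active_ids = {c.compound_id for c in calls if c.is_active}
        actives = [c for c in compounds if c.compound_id in active_ids]
        actives_kept, active_fps = _fps_of(actives)
        stage_rows, pair_rows = [], []
        for panel in panels:
            _, panel_fps = _fps_of(panel.drugs)
            rep = stage_report(
                actives_kept, panel, threshold=config.tc_threshold,
                active_fps=active_fps, panel_fps=panel_fps,
            )
            summary.similarity[panel.stage] = {
                "n_similar": rep.n_similar,
                "percent": rep.percent_similar,
            }
            stage_rows.append(
                {
                    "stage": panel.stage,
                    "n_actives": rep.n_actives,
                    "n_similar": rep.n_similar,
                    "percent_similar": rep.percent_similar,
                }
            )
            pair_rows += [
                {"compound_id": c, "drug_id": d, "stage": panel.stage, "tc": t}
                for c, d, t in rep.pairs
            ]
        write_table(pd.DataFrame(stage_rows), outdir / "similarity_stages.tsv")
        write_table(pd.DataFrame(pair_rows), outdir / "similarity_pairs.tsv")

        stage = "properties_fragments"
        approved = next((p for p in panels if p.stage == "approved"), panels[-1])
        props = pd.concat(
            [
                _property_table(actives_kept, "predicted_active"),
                _property_table(approved.drugs, "approved_drug"),
            ],
            ignore_index=True,
        )
        write_table(props, outdir / "properties.tsv")
        fragment_dict = (
            FragmentDictionary.from_tsv(config.fragment_dictionary_path)
            if config.fragment_dictionary_path
            else FragmentDictionary.default()
        )
        if actives_kept and approved.drugs:
            frag = frequency_table(actives_kept, approved.drugs, fragment_dict)
            write_table(frag, outdir / "fragments.tsv")

        stage = "network"
        sig_ids = {r.plant_id for r in results if r.significant}
        sig_plants = [p for p in plants if p.plant_id in sig_ids]
        net = build_network(
            sig_plants, panels, compounds, calls=calls,
            threshold=config.tc_threshold,
            actives_only=config.network_actives_only,
        )
        write_network(net, outdir / "network")
        comps = connected_components(net)
        comp_rows = [
            {"component": i + 1, "size": len(comp), "node": node}
            for i, comp in enumerate(comps)
            for node in comp
        ]
        write_table(pd.DataFrame(comp_rows), outdir / "components.tsv")
        summary.n_network_plants = len(net.plant_nodes)
        summary.n_network_drugs = len(net.drug_nodes)
        summary.n_network_edges = net.n_edges
        summary.n_components = len(comps)
    except PhytoscreenError as exc:
        logger.error("pipeline aborted in stage %r: %s", stage, exc)
        raise

    summary.outputs = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        if p.name != "summary.json"
    )
    summary.to_json(outdir / "summary.json")
    logger.info("pipeline done; %d artifacts in %s", len(summary.outputs), outdir)
    return summary
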