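"""Synthetic plant-compound libraries, reference sets and drug panels with
known ground truth, so every pipeline stage is testable without licensed
databases.

The generator uses a scaffold-decoration grammar: each compound is a core
scaffold SMILES flanked by a substituent prefix and suffix drawn from fixed
lists, with the valid (prefix, suffix) combinations enumerated once per
scaffold. This guarantees chemical validity and gives controllable MACCS
similarity structure:

* **active scaffolds** — four natural-product-like cores (steroid, triterpene
  fragment, saponin-type pentacycle, pyranose glycoside). Variants of one
  scaffold are mutually similar (Tc typically >= 0.7), so actives cluster.
* **isolated scaffold** — a morphinan-like alkaloid core used only by a small
  designated set of plants and two approved drugs; it is structurally distant
  (Tc < 0.7) from every other class, planting an isolated sub-network that
  component detection must recover.
* **decoy scaffolds** — eight synthetic-drug-like chemotypes (sulfonamide,
  indole ester, pteridine, phenothiazine, aryl amide, esters, azoles) distant
  from all drug scaffolds; they provide inactive compounds and the decoy null
  for the activity model. Their cores are sized so decoy variant clusters are
  about as tight as active clusters, keeping similarity density uninformative
  about the class label.
* **drug-only scaffolds** — flavone and xanthone cores that appear in panels
  but never in the library, so part of every panel resembles no library
  compound.

Panel coverage is controlled structurally: drugs derive from the first
``round(approved_coverage * 4)`` active scaffolds, so with the default 0.75
the glycoside scaffold has no corresponding drugs and roughly a quarter of
true actives fall below Tc 0.70 to every panel drug.

For purely statistical experiments on the enrichment stage (family-wise error
under the null, recovery power) :func:`generate_label_experiment` draws only
plant sizes and Bernoulli active labels — no molecules — which makes hundreds
of replicates cheap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem

from .activity import ActivityCall
from .errors import ConfigurationError
from .io_chem import CompoundRecord, DrugPanel, PlantRecord, write_smiles_file

logger = logging.getLogger(__name__)

ACTIVE_SCAFFOLDS: dict[str, str] = {
    "steroid": "CC12CCC3C(CCC4CC(O)CCC34C)C1CCC2O",
    "triterpene": "CC1(C)CCC2(C)CCC3(C)C(CCC4C3CCC3(C)CCC(O)CC43C)C2C1",
    "saponin": "CC1CCC2(CCC3(C)C(C2C1)CCC1C3CCC2(C)C1CCC2O)C",
    "glycoside": "OCC1OC(O)C(O)C(O)C1O",
}

ISOLATED_SCAFFOLD: dict[str, str] = {
    "morphinan": "CN1CCC23CCCCC2C1CC1=CC=C(O)C=C13",
}

DECOY_SCAFFOLDS: dict[str, str] = {
    "sulfa_anilide": "CC(=O)Nc1ccc(S(=O)(=O)Nc2ncccn2)cc1",
    "indole_ester": "CCOC(=O)c1c[nH]c2ccccc12",
    "benzyl_pyridone": "O=c1ccccn1Cc1ccccc1",
    "fatty_ester": "CCCCCCCCCC(=O)OCCCC",
    "benzylazole": "c1ccn(Cc2ccccc2)c1",
    "pteridine": "Nc1nc2ncc(CNc3ccccc3)nc2c(=O)[nH]1",
    "phenothiazine": "CN1c2ccccc2Sc2ccccc21",
    "procainamide": "CCN(CC)CCNC(=O)c1ccc(N)cc1",
}

DRUG_ONLY_SCAFFOLDS: dict[str, str] = {
    "flavone": "c1ccc(-c2cc(=O)c3ccccc3o2)cc1",
    "xanthone": "c1ccc2c(c1)Oc1ccccc1C2=O",
}

PREFIXES = ["", "C", "CC", "OC", "CO", "OCC", "NC", "CC(C)", "OC(=O)C", "COC"]
SUFFIXES = ["", "O", "C", "CC", "CO", "OC(C)=O", "C(C)C", "N", "CCO", "C(=O)O"]

FAMILIES = [
    "Araliaceae", "Asteraceae", "Boraginaceae", "Ranunculaceae", "Rosaceae",
    "Lamiaceae", "Fabaceae", "Apiaceae", "Apocynaceae", "Liliaceae",
]

_VARIANT_CACHE: dict[str, list[str]] = {}


def scaffold_variants(core: str) -> list[str]:
    """All chemically valid prefix+core+suffix decorations of a scaffold."""
    if core not in _VARIANT_CACHE:
        valid = []
        for p in PREFIXES:
            for s in SUFFIXES:
                smi = p + core + s
                if Chem.MolFromSmiles(smi) is not None:
                    valid.append(smi)
        if not valid:
            raise ConfigurationError(f"scaffold {core!r} admits no valid decoration")
        _VARIANT_CACHE[core] = valid
    return _VARIANT_CACHE[core]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults emulate the shape of a large
    natural-product screen (about a quarter of the library active, staged
    panels of 127/425/219 drugs, three-quarters of actives drug-like)."""

    n_plants: int = 200
    compounds_per_plant: tuple[int, int] = (10, 70)  # inclusive range
    background_active_fraction: float = 0.25
    n_enriched_plants: int = 6
    enriched_active_fraction: float = 0.9
    enriched_plant_size: int = 20
    n_isolated_plants: int = 3
    isolated_plant_size: int = 20
    panel_sizes: dict = field(
        default_factory=lambda: {"preclinical": 127, "clinical": 425, "approved": 219}
    )
    approved_coverage: float = 0.75  # target fraction of actives near the approved panel
    drug_panel_library_fraction: float = 0.8  # rest from drug-only scaffolds
    n_isolated_drugs: int = 2
    drug_perturbation: str = "decorate"  # "copy" | "decorate" | "swap"
    overlap_fraction: float = 0.05  # chance a compound is shared with a 2nd plant
    n_reference_actives: int = 600
    n_reference_decoys: int = 600
    seed: int = 0

    def validate(self) -> None:
        for name in ("background_active_fraction", "enriched_active_fraction",
                     "approved_coverage", "overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_enriched_plants + self.n_isolated_plants > self.n_plants:
            raise ConfigurationError(
                f"enriched ({self.n_enriched_plants}) + isolated "
                f"({self.n_isolated_plants}) plants exceed n_plants ({self.n_plants})"
            )
        if self.drug_perturbation not in ("copy", "decorate", "swap"):
            raise ConfigurationError(
                f"drug_perturbation must be copy/decorate/swap, got {self.drug_perturbation!r}"
            )
        lo, hi = self.compounds_per_plant
        if not (0 < lo <= hi):
            raise ConfigurationError(f"bad compounds_per_plant range {self.compounds_per_plant}")


@dataclass
class GroundTruth:
    """What the generator planted: labels and the intended network layout."""

    active_ids: set[str]
    enriched_plant_ids: list[str]
    isolated_plant_ids: list[str]
    isolated_drug_ids: list[str]
    covered_scaffolds: list[str]
    scaffold_by_compound: dict[str, str]
    target_approved_coverage: float
    planned_components: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["active_ids"] = sorted(self.active_ids)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True), encoding="utf-8")


@dataclass
class SyntheticDataset:
    compounds: list[CompoundRecord]
    plants: list[PlantRecord]
    reference_actives: list[CompoundRecord]
    reference_decoys: list[CompoundRecord]
    panels: list[DrugPanel]
    truth: GroundTruth


def _pick_variant(rng: np.random.Generator, core: str) -> str:
    variants = scaffold_variants(core)
    return variants[rng.integers(len(variants))]


def generate_library(config: GeneratorConfig):
    """Generate (compounds, plants, truth). Deterministic under config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    main_scaffolds = list(ACTIVE_SCAFFOLDS)
    iso_scaffold = next(iter(ISOLATED_SCAFFOLD))
    decoy_scaffolds = list(DECOY_SCAFFOLDS)
    enrichment_on = (
        config.enriched_active_fraction > config.background_active_fraction
    )

    compounds: list[CompoundRecord] = []
    plants: list[PlantRecord] = []
    active_ids: set[str] = set()
    scaffold_by_compound: dict[str, str] = {}
    # per-class pools for the cross-plant overlap draw
    pool: dict[tuple[bool, bool], list[str]] = {}

    enriched_plant_ids: list[str] = []
    isolated_plant_ids: list[str] = []
    counter = 0

    for i in range(config.n_plants):
        plant_id = f"P{i + 1:04d}"
        is_enriched = i < config.n_enriched_plants
        is_isolated = (
            config.n_enriched_plants <= i < config.n_enriched_plants + config.n_isolated_plants
        )
        if is_enriched:
            size = config.enriched_plant_size
            frac = config.enriched_active_fraction
        elif is_isolated:
            size = config.isolated_plant_size
            frac = config.enriched_active_fraction
        else:
            lo, hi = config.compounds_per_plant
            size = int(rng.integers(lo, hi + 1))
            frac = config.background_active_fraction
        plant = PlantRecord(
            plant_id=plant_id,
            plant_name=f"Plantus synthetica {i + 1}",
            family=FAMILIES[int(rng.integers(len(FAMILIES)))],
        )
        if is_enriched and enrichment_on:
            enriched_plant_ids.append(plant_id)
        if is_isolated:
            isolated_plant_ids.append(plant_id)

        for _ in range(size):
            is_active = bool(rng.random() < frac)
            key = (is_active, is_isolated)
            if (
                config.overlap_fraction > 0
                and pool.get(key)
                and rng.random() < config.overlap_fraction
            ):
                shared = pool[key][int(rng.integers(len(pool[key])))]
                if shared not in plant.compound_ids:
                    plant.compound_ids.add(shared)
                    continue
            counter += 1
            cid = f"C{counter:06d}"
            if is_active:
                scaffold = (
                    iso_scaffold
                    if is_isolated
                    else main_scaffolds[int(rng.integers(len(main_scaffolds)))]
                )
                core = {**ACTIVE_SCAFFOLDS, **ISOLATED_SCAFFOLD}[scaffold]
                active_ids.add(cid)
            else:
                scaffold = decoy_scaffolds[int(rng.integers(len(decoy_scaffolds)))]
                core = DECOY_SCAFFOLDS[scaffold]
            smiles = _pick_variant(rng, core)
            compounds.append(CompoundRecord(compound_id=cid, smiles=smiles))
            scaffold_by_compound[cid] = scaffold
            plant.compound_ids.add(cid)
            pool.setdefault(key, []).append(cid)
        plants.append(plant)

    n_covered = int(round(config.approved_coverage * len(main_scaffolds)))
    truth = GroundTruth(
        active_ids=active_ids,
        enriched_plant_ids=enriched_plant_ids,
        isolated_plant_ids=isolated_plant_ids,
        isolated_drug_ids=[],
        covered_scaffolds=main_scaffolds[:n_covered],
        scaffold_by_compound=scaffold_by_compound,
        target_approved_coverage=config.approved_coverage,
    )
    logger.info(
        "generated %d compounds in %d plants (%.1f%% active; %d enriched, %d isolated plants)",
        len(compounds), len(plants), 100 * len(active_ids) / max(len(compounds), 1),
        len(enriched_plant_ids), len(isolated_plant_ids),
    )
    return compounds, plants, truth


def generate_reference_sets(config: GeneratorConfig):
    """Reference actives (all active scaffolds incl. isolated) and decoys.

    Drawn with a seed offset so reference molecules are fresh, not library
    copies.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 10_007)
    all_active = {**ACTIVE_SCAFFOLDS, **ISOLATED_SCAFFOLD}
    names = list(all_active)
    actives = [
        CompoundRecord(
            compound_id=f"REFA{i + 1:04d}",
            smiles=_pick_variant(rng, all_active[names[i % len(names)]]),
        )
        for i in range(config.n_reference_actives)
    ]
    decoy_names = list(DECOY_SCAFFOLDS)
    decoys = [
        CompoundRecord(
            compound_id=f"DECOY{i + 1:05d}",
            smiles=_pick_variant(rng, DECOY_SCAFFOLDS[decoy_names[i % len(decoy_names)]]),
        )
        for i in range(config.n_reference_decoys)
    ]
    return actives, decoys


def generate_drug_panels(
    config: GeneratorConfig, truth: GroundTruth, compounds=None
):
    """Generate staged drug panels near the covered active scaffolds.

    Returns ``(panels, truth)`` with the truth updated in place: isolated drug
    ids and the planned two-component layout of the plant-drug network.

    ``drug_perturbation`` controls distance from the actives: "copy" takes
    drug structures verbatim from library actives (zero perturbation, Tc = 1;
    needs ``compounds``), "decorate" (default) re-decorates the covered
    cores, "swap" replaces every scaffold with a decoy scaffold so coverage
    collapses toward zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 20_011)
    copy_pool: list[str] = []
    if config.drug_perturbation == "copy":
        if compounds is None:
            raise ConfigurationError("drug_perturbation='copy' needs the library compounds")
        copy_pool = sorted(
            c.smiles
            for c in compounds
            if c.compound_id in truth.active_ids
            and truth.scaffold_by_compound.get(c.compound_id) in truth.covered_scaffolds
        )
        if not copy_pool:
            raise ConfigurationError("no covered-scaffold actives available to copy")
    covered_cores = [ACTIVE_SCAFFOLDS[s] for s in truth.covered_scaffolds]
    if config.drug_perturbation == "swap":
        covered_cores = [DECOY_SCAFFOLDS[s] for s in list(DECOY_SCAFFOLDS)[:3]]
    druonly_cores = list(DRUG_ONLY_SCAFFOLDS.values())
    iso_core = next(iter(ISOLATED_SCAFFOLD.values()))

    prefix = {"preclinical": "pre", "clinical": "clin", "approved": "appr"}
    panels = []
    isolated_drug_ids: list[str] = []
    for stage in ("preclinical", "clinical", "approved"):
        size = config.panel_sizes[stage]
        drugs = []
        n_iso = config.n_isolated_drugs if stage == "approved" else 0
        n_lib_like = int(round(config.drug_panel_library_fraction * (size - n_iso)))
        for j in range(size):
            did = f"{prefix[stage]}{j + 1:04d}"
            if j >= size - n_iso:
                core = iso_core
                isolated_drug_ids.append(did)
            elif j < n_lib_like and covered_cores:
                core = covered_cores[j % len(covered_cores)]
            else:
                core = druonly_cores[j % len(druonly_cores)]
            if (
                config.drug_perturbation == "copy"
                and core not in druonly_cores
                and core != iso_core
            ):
                smiles = copy_pool[int(rng.integers(len(copy_pool)))]
            else:
                smiles = _pick_variant(rng, core)
            drugs.append(CompoundRecord(compound_id=did, smiles=smiles))
        panels.append(DrugPanel(stage=stage, drugs=drugs))

    truth.isolated_drug_ids = isolated_drug_ids
    truth.planned_components = [
        {
            "kind": "main",
            "plants": sorted(
                set(truth.enriched_plant_ids) - set(truth.isolated_plant_ids)
            ),
        },
        {
            "kind": "isolated",
            "plants": sorted(truth.isolated_plant_ids),
            "drugs": sorted(isolated_drug_ids),
        },
    ]
    return panels, truth


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """One-call generation of the full synthetic study."""
    if config is None:
        config = GeneratorConfig()
    compounds, plants, truth = generate_library(config)
    ref_actives, ref_decoys = generate_reference_sets(config)
    panels, truth = generate_drug_panels(config, truth, compounds)
    return SyntheticDataset(
        compounds=compounds,
        plants=plants,
        reference_actives=ref_actives,
        reference_decoys=ref_decoys,
        panels=panels,
        truth=truth,
    )


def generate_label_experiment(
    n_plants: int,
    plant_size_range: tuple[int, int],
    active_fraction: float,
    enriched_plants: int = 0,
    enriched_size: int = 30,
    enriched_fraction: float | None = None,
    seed: int = 0,
):
    """Plants + activity calls with Bernoulli labels and no molecules.

    This is the statistical skeleton of the library generator (same plant
    size model, same label model) for null/power simulation of the
    enrichment stage at hundreds of replicates.
    """
    rng = np.random.default_rng(seed)
    plants: list[PlantRecord] = []
    calls: list[ActivityCall] = []
    counter = 0
    for i in range(n_plants):
        if i < enriched_plants:
            size = enriched_size
            frac = enriched_fraction if enriched_fraction is not None else active_fraction
        else:
            size = int(rng.integers(plant_size_range[0], plant_size_range[1] + 1))
            frac = active_fraction
        plant = PlantRecord(
            plant_id=f"P{i + 1:04d}", plant_name=f"plant {i + 1}", family="na"
        )
        for _ in range(size):
            counter += 1
            cid = f"C{counter:06d}"
            active = bool(rng.random() < frac)
            calls.append(
                ActivityCall(
                    compound_id=cid,
                    score=float(rng.random()),
                    p_value=0.01 if active else 0.5,
                    is_active=active,
                )
            )
            plant.compound_ids.add(cid)
        plants.append(plant)
    return plants, calls


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write a dataset in exactly the formats the readers consume."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "library": outdir / "library.smi",
        "annotation": outdir / "annotation.tsv",
        "reference_actives": outdir / "reference_actives.smi",
        "reference_decoys": outdir / "reference_decoys.smi",
        "panels": outdir / "drug_panels.tsv",
        "truth": outdir / "truth.json",
    }
    write_smiles_file(dataset.compounds, paths["library"])
    rows = [
        {
            "compound_id": cid,
            "plant_id": p.plant_id,
            "plant_name": p.plant_name,
            "family": p.family,
        }
        for p in dataset.plants
        for cid in sorted(p.compound_ids)
    ]
    pd.DataFrame(rows).to_csv(paths["annotation"], sep="\t", index=False)
    write_smiles_file(dataset.reference_actives, paths["reference_actives"])
    write_smiles_file(dataset.reference_decoys, paths["reference_decoys"])
    panel_rows = [
        {"drug_id": d.compound_id, "smiles": d.smiles, "stage": panel.stage}
        for panel in dataset.panels
        for d in panel.drugs
    ]
    pd.DataFrame(panel_rows).to_csv(paths["panels"], sep="\t", index=False)
    dataset.truth.to_json(paths["truth"])
    return paths
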