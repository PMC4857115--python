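"""Similarity profiling of predicted actives against staged drug panels.

Two molecules count as structurally similar when the Tanimoto coefficient of
their MACCS fingerprints is at least 0.70 (inclusive threshold). For each
development stage the report counts how many predicted actives have a
max-similarity drug at or above the threshold, plus the above-threshold pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .chem_core import Fingerprint, fingerprint_matrix, tanimoto_matrix
from .errors import InputError
from .io_chem import DrugPanel

logger = logging.getLogger(__name__)

DEFAULT_TC_THRESHOLD = 0.70


@dataclass
class SimilarityReport:
    stage: str
    n_actives: int
    n_similar: int
    percent_similar: int
    pairs: list[tuple[str, str, float]] = field(default_factory=list)


def round_percent(count: int, total: int) -> int:
    """100*count/total rounded half away from zero to the nearest integer."""
    if total == 0:
        return 0
    return int(math.floor(100.0 * count / total + 0.5))


def max_similarity(fp: Fingerprint, panel: DrugPanel) -> tuple[str, float]:
    """Best (drug_id, Tc) of a fingerprint over a panel; ties break to the
    lexicographically smallest drug id."""
    if not panel.drugs:
        raise InputError(f"empty {panel.stage} panel")
    panel_fps = fingerprint_matrix([d.smiles for d in panel.drugs])
    tcs = tanimoto_matrix(fp.bits[None, :], panel_fps)[0]
    best = tcs.max()
    ties = [panel.drugs[i].compound_id for i in np.flatnonzero(tcs == best)]
    return min(ties), float(best)


def stage_report(
    actives,
    panel: DrugPanel,
    threshold: float = DEFAULT_TC_THRESHOLD,
    active_fps: np.ndarray | None = None,
    panel_fps: np.ndarray | None = None,
) -> SimilarityReport:
    """Per-stage similarity coverage of predicted actives.

    ``actives`` is a list of CompoundRecord; precomputed fingerprint matrices
    may be passed to avoid recomputation across stages.
    """
    if not panel.drugs:
        raise InputError(f"empty {panel.stage} panel")
    if active_fps is None:
        active_fps = fingerprint_matrix([c.smiles for c in actives])
    if panel_fps is None:
        panel_fps = fingerprint_matrix([d.smiles for d in panel.drugs])
    T = tanimoto_matrix(active_fps, panel_fps)
    similar_mask = T.max(axis=1) >= threshold if T.size else np.zeros(len(actives), bool)
    n_similar = int(similar_mask.sum())

    pairs = []
    for i, j in zip(*np.nonzero(T >= threshold)):
        pairs.append(
            (actives[i].compound_id, panel.drugs[j].compound_id, float(T[i, j]))
        )
    pairs.sort()

    report = SimilarityReport(
        stage=panel.stage,
        n_actives=len(actives),
        n_similar=n_similar,
        percent_similar=round_percent(n_similar, len(actives)),
        pairs=pairs,
    )
    logger.info(
        "similarity: %d/%d actives (%d%%) within Tc >= %.2f of the %s panel",
        n_similar, len(actives), report.percent_similar, threshold, panel.stage,
    )
    return report
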