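"""Ligand-based anti-cancer activity calling.

A compound is scored against a reference set of known actives with a
frequency-weighted fingerprint similarity, and the score is converted to an
empirical P-value against the score distribution of a decoy (presumed
inactive) set. A compound is called active when P < alpha (default 0.05).

The scorer combines two sources of evidence:

* per-bit weights  w(b) = ln((f_active(b) + eps) / (f_decoy(b) + eps)),
  clipped to [-w_max, w_max], measuring how over-represented each MACCS key
  is among the actives relative to the decoys;
* a weighted Tanimoto between query q and reference active a,
  wTc(q, a) = sum_b w+(b)[b in q and a] / sum_b w+(b)[b in q or a]
  with positive bit masses w+(b) = exp(w(b));
* hybrid score = 0.5 * max_a wTc(q, a) + 0.5 * mean of the top-5 wTc(q, a),
  i.e. nearest-neighbour evidence blended with neighbourhood evidence.

The empirical P uses the add-one estimator p = (1 + #{null >= s}) / (1 + K)
over the K decoy scores, so P is never exactly zero and ties count toward the
tail (conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chem_core import N_MACCS_BITS, Fingerprint, compute_fingerprint
from .errors import ConfigurationError, ContractViolation, StructureError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
EPSILON = 0.01
W_MAX = 5.0
MIN_ACTIVES = 10
MIN_DECOYS = 200
TOP_K = 5


@dataclass
class ActivityModel:
    """Fitted activity scorer: reference actives, bit weights, null scores."""

    active_fps: np.ndarray  # (n_actives, 166) bool
    bit_weights: np.ndarray  # (166,) float, clipped to [-W_MAX, W_MAX]
    null_scores: np.ndarray  # sorted ascending, scores of the decoys

    @property
    def min_p(self) -> float:
        return 1.0 / (1.0 + len(self.null_scores))


@dataclass(frozen=True)
class ActivityCall:
    compound_id: str
    score: float
    p_value: float
    is_active: bool


def _as_matrix(fps) -> np.ndarray:
    if isinstance(fps, np.ndarray):
        mat = fps
    else:
        mat = np.vstack([f.bits if isinstance(f, Fingerprint) else f for f in fps])
    if mat.ndim != 2 or mat.shape[1] != N_MACCS_BITS:
        raise ContractViolation(f"expected (n, {N_MACCS_BITS}) fingerprints, got {mat.shape}")
    return mat.astype(bool)


def fit_activity_model(
    actives,
    decoys,
    *,
    min_actives: int = MIN_ACTIVES,
    min_decoys: int = MIN_DECOYS,
    epsilon: float = EPSILON,
    w_max: float = W_MAX,
) -> ActivityModel:
    """Fit bit weights from active/decoy key frequencies and build the null.

    The decoy floor bounds the resolution of the empirical P-value: with at
    least ``min_decoys`` decoys the smallest reportable P is below
    1/(min_decoys+1).
    """
    A = _as_matrix(actives)
    D = _as_matrix(decoys)
    if A.shape[0] < min_actives:
        raise ConfigurationError(
            f"need at least {min_actives} reference actives, got {A.shape[0]}"
        )
    if D.shape[0] < min_decoys:
        raise ConfigurationError(
            f"need at least {min_decoys} decoys, got {D.shape[0]}"
        )
    f_active = A.mean(axis=0)
    f_decoy = D.mean(axis=0)
    weights = np.clip(
        np.log((f_active + epsilon) / (f_decoy + epsilon)), -w_max, w_max
    )
    model = ActivityModel(
        active_fps=A, bit_weights=weights, null_scores=np.empty(0)
    )
    model.null_scores = np.sort(score_batch(model, D))
    return model


def score_batch(model: ActivityModel, fps) -> np.ndarray:
    """Hybrid scores for a batch of query fingerprints (vectorized)."""
    if model.active_fps.size == 0:
        raise ContractViolation("activity model has an empty reference active set")
    Q = _as_matrix(fps)
    w_pos = np.exp(model.bit_weights)  # positive bit masses
    Aw = model.active_fps * w_pos  # (nA, 166)
    a_mass = Aw.sum(axis=1)  # (nA,)
    q_mass = (Q * w_pos).sum(axis=1)  # (nQ,)
    inter = Q.astype(float) @ Aw.T  # (nQ, nA) weighted intersection
    union = q_mass[:, None] + a_mass[None, :] - inter
    wtc = np.divide(inter, union, out=np.zeros_like(inter), where=union > 0)
    k = min(TOP_K, wtc.shape[1])
    top = np.sort(wtc, axis=1)[:, -k:]
    return 0.5 * wtc.max(axis=1) + 0.5 * top.mean(axis=1)


def score_compound(model: ActivityModel, fp) -> float:
    """Hybrid similarity score of one query against the reference actives."""
    bits = fp.bits if isinstance(fp, Fingerprint) else fp
    return float(score_batch(model, bits[None, :])[0])


def empirical_pvalue(model: ActivityModel, score: float) -> float:
    """Add-one upper-tail probability of ``score`` under the decoy null."""
    nulls = model.null_scores
    n_ge = len(nulls) - int(np.searchsorted(nulls, score, side="left"))
    return (1 + n_ge) / (1 + len(nulls))


def predict_library(
    model: ActivityModel, library, alpha: float = DEFAULT_ALPHA
) -> list[ActivityCall]:
    """Score every parseable library compound and call actives at P < alpha."""
    ids, fps = [], []
    n_bad = 0
    for rec in library:
        try:
            fps.append(compute_fingerprint(rec.smiles).bits)
            ids.append(rec.compound_id)
        except StructureError:
            n_bad += 1
            logger.warning("skipping unparseable compound %s", rec.compound_id)
    if n_bad:
        logger.info("skipped %d unparseable compounds", n_bad)
    if not ids:
        return []
    scores = score_batch(model, np.vstack(fps))
    nulls = model.null_scores
    n_ge = len(nulls) - np.searchsorted(nulls, scores, side="left")
    pvals = (1 + n_ge) / (1 + len(nulls))
    calls = [
        ActivityCall(
            compound_id=cid,
            score=float(s),
            p_value=float(p),
            is_active=bool(p < alpha),
        )
        for cid, s, p in zip(ids, scores, pvals)
    ]
    frac = np.mean([c.is_active for c in calls])
    logger.info(
        "activity screen: %d/%d compounds called active (%.1f%%) at P < %g",
        sum(c.is_active for c in calls), len(calls), 100 * frac, alpha,
    )
    return calls
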