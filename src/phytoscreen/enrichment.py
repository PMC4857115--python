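"""Activity enrichment analysis (ACEA): per-plant hypergeometric test.

For a library of N compounds of which n are predicted active, a plant holding
m compounds of which k are predicted active gets the upper-tail probability

    P = P(X >= k),   X ~ Hypergeometric(population N, successes n, draws m),

i.e. the chance that a random draw of m compounds from the library contains at
least k actives. Because one test is run per plant, P-values are
Bonferroni-adjusted, P_adj = min(1, P * Ng) with Ng the number of plants
tested, and a plant is called significantly enriched when P_adj < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom

from .activity import ActivityCall
from .errors import ContractViolation
from .io_chem import PlantRecord

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_ADJ = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    plant_id: str
    plant_name: str
    family: str
    N: int  # compounds in the library
    n: int  # predicted actives in the library
    m: int  # compounds in this plant
    k: int  # predicted actives in this plant
    p: float
    p_adj: float
    significant: bool


def hypergeom_upper_tail(N: int, n: int, m: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, n, m).

    k = 0 returns exactly 1.0 (the whole distribution).
    """
    if not 0 <= n <= N:
        raise ContractViolation(f"need 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= m <= N:
        raise ContractViolation(f"need 0 <= m <= N, got m={m}, N={N}")
    if not 0 <= k <= min(n, m):
        raise ContractViolation(f"need 0 <= k <= min(n, m), got k={k}, n={n}, m={m}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, n, m))


def bonferroni_adjust(p: float, Ng: int) -> float:
    """Bonferroni family-wise adjustment, capped at 1."""
    if not 0.0 <= p <= 1.0:
        raise ContractViolation(f"p must be in [0, 1], got {p}")
    if Ng < 1:
        raise ContractViolation(f"Ng must be >= 1, got {Ng}")
    return min(1.0, p * Ng)


def run_acea(
    plants: list[PlantRecord],
    calls: list[ActivityCall],
    alpha_adj: float = DEFAULT_ALPHA_ADJ,
    min_m: int = 0,
) -> list[EnrichmentResult]:
    """Enrichment test for every plant against the library-wide active call.

    N and n count each distinct compound once at the library level; m and k
    count at the plant level, so a compound shared by several plants
    contributes to each of their (m, k) but only once to (N, n). Ng is the
    number of plants tested (all plants unless ``min_m`` excludes small ones).
    Results come back sorted by (p_adj ascending, plant_name ascending) with
    every plant present, significant or not.
    """
    call_by_id = {c.compound_id: c for c in calls}
    N = len(call_by_id)
    n = sum(1 for c in call_by_id.values() if c.is_active)

    tested = [p for p in plants if p.m >= min_m] if min_m > 0 else list(plants)
    Ng = len(tested)
    results = []
    for plant in tested:
        members = [cid for cid in plant.compound_ids if cid in call_by_id]
        m = len(members)
        k = sum(1 for cid in members if call_by_id[cid].is_active)
        if m == 0:
            logger.warning("plant %s has no scored compounds; untestable (p=1)", plant.plant_id)
            p = 1.0
        else:
            p = hypergeom_upper_tail(N, n, m, k)
        p_adj = bonferroni_adjust(p, Ng)
        # alpha_adj >= 1 disables the filter: the cap at 1 would otherwise
        # exclude plants sitting exactly on the cap under the strict '<'
        significant = p_adj < alpha_adj or alpha_adj >= 1.0
        results.append(
            EnrichmentResult(
                plant_id=plant.plant_id,
                plant_name=plant.plant_name,
                family=plant.family,
                N=N, n=n, m=m, k=k,
                p=p, p_adj=p_adj,
                significant=significant,
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.plant_name))
    n_sig = sum(r.significant for r in results)
    logger.info(
        "ACEA: %d/%d plants significantly enriched (P_adj < %g; Ng=%d, N=%d, n=%d)",
        n_sig, Ng, alpha_adj, Ng, N, n,
    )
    return results
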