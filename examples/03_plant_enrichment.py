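"""Find plants significantly enriched in predicted-active compounds (ACEA).

For each plant holding m compounds of which k are predicted active, the
upper-tail hypergeometric probability of seeing >= k actives by chance is
Bonferroni-adjusted over all plants; P_adj < 0.05 flags an anti-cancer plant
candidate.
"""

from phytoscreen import (
    GeneratorConfig,
    fit_activity_model,
    generate_dataset,
    predict_library,
    run_acea,
)
from phytoscreen.pipeline import _fps_of

dataset = generate_dataset(GeneratorConfig(seed=1))
_, ra = _fps_of(dataset.reference_actives)
_, rd = _fps_of(dataset.reference_decoys)
calls = predict_library(fit_activity_model(ra, rd), dataset.compounds)

results = run_acea(dataset.plants, calls, alpha_adj=0.05)
significant = [r for r in results if r.significant]
print(f"{len(significant)}/{len(results)} plants significant (P_adj < 0.05)")
print(f"{'plant':24s} {'m':>4s} {'k':>4s} {'P_adj':>10s}")
for r in significant:
    print(f"{r.plant_name:24s} {r.m:4d} {r.k:4d} {r.p_adj:10.2e}")
planted = set(dataset.truth.enriched_plant_ids) | set(dataset.truth.isolated_plant_ids)
hit = sum(1 for r in significant if r.plant_id in planted)
print(f"{hit}/{len(planted)} plants the generator enriched were recovered; "
      f"{len(significant) - hit} false discoveries")
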