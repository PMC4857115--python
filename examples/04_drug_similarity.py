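"""Profile predicted actives against drug panels at three development stages.

Two molecules count as similar when their 166-bit MACCS fingerprints have
Tanimoto >= 0.70; the per-stage percentage says how drug-like the predicted
actives are, and its complement flags candidates for innovative (dissimilar)
chemistry.
"""

from phytoscreen import (
    GeneratorConfig,
    fit_activity_model,
    generate_dataset,
    max_similarity,
    predict_library,
    stage_report,
)
from phytoscreen.chem_core import compute_fingerprint
from phytoscreen.pipeline import _fps_of

dataset = generate_dataset(GeneratorConfig(seed=1))
_, ra = _fps_of(dataset.reference_actives)
_, rd = _fps_of(dataset.reference_decoys)
calls = predict_library(fit_activity_model(ra, rd), dataset.compounds)
active_ids = {c.compound_id for c in calls if c.is_active}
actives = [c for c in dataset.compounds if c.compound_id in active_ids]

for panel in dataset.panels:
    rep = stage_report(actives, panel, threshold=0.70)
    print(f"{panel.stage:12s}: {rep.n_similar}/{rep.n_actives} actives "
          f"({rep.percent_similar}%) within Tc 0.70 of a drug")

fp = compute_fingerprint(actives[0].smiles)
drug, tc = max_similarity(fp, dataset.panels[-1])
print(f"nearest approved drug to {actives[0].compound_id}: {drug} (Tc={tc:.2f})")
print("compounds below the threshold for every stage are the structurally "
      "novel fraction of the screen")
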