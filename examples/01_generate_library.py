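"""Generate a synthetic plant-compound library with known ground truth.

The generator emulates the shape of a large natural-product screen: ~25% of
compounds truly active, a handful of plants deliberately enriched in actives,
and staged drug panels structurally near the active scaffolds.
"""

from phytoscreen import GeneratorConfig, generate_dataset, write_dataset

config = GeneratorConfig(seed=1)
dataset = generate_dataset(config)

n = len(dataset.compounds)
n_active = len(dataset.truth.active_ids)
print(f"library: {n} compounds in {len(dataset.plants)} plants")
print(f"truly active: {n_active} ({100 * n_active / n:.1f}%) "
      f"- the fraction the activity screen should rediscover")
print(f"designated enriched plants: {dataset.truth.enriched_plant_ids}")
print(f"isolated sub-network plants: {dataset.truth.isolated_plant_ids}")
for panel in dataset.panels:
    print(f"{panel.stage} panel: {len(panel.drugs)} drugs")

paths = write_dataset(dataset, "example_data")
print("files written:", ", ".join(str(p) for p in paths.values()))
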