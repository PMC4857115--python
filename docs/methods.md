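# Methods

## Overview

`phytoscreen` implements a ligand-based screen of a plant-annotated compound
library: per-compound activity calling, per-plant activity enrichment,
similarity profiling against staged drug panels, structural characterization,
and a bipartite plant–drug network. This note records the models, the
numerical choices, and what the synthetic benchmark does and does not show.

## Fingerprints and similarity

All similarity computations use the 166 public MACCS substructure keys.
RDKit emits a 167-bit vector whose bit 0 is unused; it is dropped, so a
fingerprint is exactly the 166 keys. The Tanimoto coefficient is
`Tc = |A∩B| / |A∪B|` over set bits; the degenerate case of two all-zero
fingerprints is defined as `Tc = 0`, since the absence of shared substructure
evidence should never count as similarity. Two compounds are "similar" when
`Tc ≥ 0.70` (inclusive). The fingerprint is fixed — no configurable
alternative — because the 0.70 threshold is only meaningful for MACCS keys.

## Activity model

The activity stage is a similarity-based classifier with an empirical null:

* **Bit weights.** `w(b) = ln((f_active(b)+ε) / (f_decoy(b)+ε))`, with
  `ε = 0.01` and clipping to `[−5, 5]`. Keys over-represented among known
  actives get positive weight; ε bounds the odds ratio when a key is absent
  from one set, and the clip caps any single key's influence at `e^5 ≈ 148×`.
* **Weighted Tanimoto.** `wTc(q,a) = Σ_b w⁺(b)·[b∈q∧a] / Σ_b w⁺(b)·[b∈q∨a]`
  with positive bit masses `w⁺(b) = exp(w(b))`, so informative keys dominate
  both intersection and union.
* **Hybrid score.** `0.5·max_a wTc + 0.5·mean(top-5 wTc)`: nearest-neighbour
  evidence blended with local-neighbourhood evidence, fixed constants for
  reproducibility. With fewer than five reference actives the mean runs over
  all of them.
* **Empirical P.** `p = (1 + #{null ≥ s}) / (1 + K)` over the `K` decoy
  scores (add-one, so `p` is never 0; ties count toward the tail, which is
  conservative). A floor of 200 decoys bounds the resolution at `p < 0.005`;
  the default benchmark uses 600, giving a minimum reportable `p ≈ 0.0017`.
* **Decision rule.** Active ⇔ `p < 0.05`. Scoring the decoys against their
  own null yields uniform P-values by construction, so the cutoff admits
  ~5% of inactives — the screen's designed false-positive rate.

## Enrichment (ACEA)

A plant with `m` compounds of which `k` are predicted active, in a library of
`N` compounds with `n` predicted actives, gets the hypergeometric upper tail
`P(X ≥ k)` with `X ~ Hypergeom(N, n, m)`; `k = 0` returns exactly 1. The tail
is computed by `scipy.stats.hypergeom.sf`, which agrees with exact rational
enumeration to better than 1e-15 relative error over all populations `N ≤ 25`
(checked in the test suite against an independent combinatorial oracle).
Compounds shared by several plants count toward each plant's `(m, k)` but
once in `(N, n)`. P-values are Bonferroni-adjusted over the `Ng` plants
tested, capped at 1 (a bare product above 1 is not a probability).
Significance uses a strict `<`; a threshold of 1.0 is treated as "keep every
plant" since the cap would otherwise exclude plants sitting exactly on it.
An optional `min_m` filter excludes small plants from the family; it defaults
to off because small plants are a power limitation, not invalid tests. Plants
with no scored compounds get `p = 1` and a log warning. Ties in `p_adj` are
ordered by plant name for deterministic output.

## Similarity profiling and percentages

Per stage, the report counts actives whose maximum Tc over the panel reaches
0.70; ties in the argmax break to the lexicographically smallest drug id.
Percentages are rounded half away from zero to the nearest integer — the
convention consistent with the printed count/percent pairs this reporting
style is drawn from. A drug listed at several stages is profiled in each
stage independently; in the network it is labelled by its most advanced
stage (approved > clinical > preclinical), since a node is coloured once.

## Properties and fragments

ALogP is RDKit's Crippen atom-contribution estimate — an approximation of
other vendors' ALogP implementations (differences of a few tenths are
expected; only the `< 5` cutoff and distribution shapes matter here).
Ring counts use the smallest set of smallest rings (SSSR); rotatable bonds
exclude amide and ring bonds. Rule-of-five bounds are strict inequalities
(HBD < 5, HBA < 10, MW < 500 Da, ALogP < 5), so a profile exactly on a bound
fails that criterion. Fragment frequency is the fraction of molecules with at
least one embedding of a SMARTS pattern — molecules are counted, not
occurrences. The shipped dictionary holds 16 named fragments
(aromatic and saturated N/O-heterocycles, carbocycles, trifluoroethane,
methyl acetate, benzene) and is user-extensible via TSV; exhaustive frequent
-subgraph mining is deliberately out of scope.

## Network

An enriched plant connects to a drug iff some compound of the plant reaches
Tc ≥ 0.70 to the drug; each edge stores its (compound, Tc) evidence pairs.
By default all annotated compounds of a plant may carry evidence, with
`actives_only=True` covering the stricter reading; the default is the more
inclusive rule because the connection criterion is about the plant's
chemistry, not the activity call. Components are computed over plant+drug
nodes; degree-0 nodes form no component (an enriched plant resembling no
drug is reported in the node table, not as a sub-network). Components sort
by size then smallest member; SIF/GraphML exports are byte-stable.

## Synthetic study design

The generator builds compounds by scaffold decoration: a core SMILES flanked
by a substituent prefix and suffix from fixed lists, with valid combinations
enumerated once per scaffold (guaranteed parseable, deterministic under a
seed). The scaffold classes and their roles:

* four **active scaffolds** (steroid, triterpene fragment, saponin-type
  pentacycle, pyranose glycoside): variants of one scaffold are mutually
  MACCS-similar, so actives form tight clusters;
* one **isolated scaffold** (morphinan-like): used only by three designated
  plants and two approved drugs, and verified structurally distant
  (max cross-class Tc < 0.7) from every other class — it plants a second
  network component that component detection must recover;
* eight **decoy scaffolds** (synthetic-drug-like chemotypes: sulfonamide,
  indole ester, pteridine, phenothiazine, aryl amides, esters, azoles):
  sources of inactive compounds and of the decoy null. Their cores are sized
  so decoy variant clusters are about as tight as active clusters; without
  that, similarity density alone predicts the class label and a
  label-permutation control does not collapse to chance;
* two **drug-only scaffolds** (flavone, xanthone): panel members resembling
  no library compound.

Default study shape: 200 plants of 10–70 compounds; background active
fraction 0.25; six designated enriched plants (20 compounds, 90% active) plus
the three isolated plants (20 compounds, 90% active); panels of 127/425/219
drugs. Plant counts and sizes were chosen so the background dominates and the
realized overall active fraction stays within a few points of the configured
0.25 despite the enriched plants. Panel drugs derive from the first
`round(0.75·4) = 3` active scaffolds, so the glycoside scaffold has no
corresponding drugs and roughly a quarter of true actives fall below Tc 0.70
to every panel — the structural mechanism behind the 0.75 coverage target
(realized ≈ 0.76). Reference sets are 600 fresh active-scaffold variants and
600 decoy-scaffold variants; the balanced pool mirrors activity predictors
trained on large assay-derived active collections and makes the
label-permutation control clean (a heavily decoy-dominated pool leaves
shuffled models systematically anti-predictive on scaffold-clustered data).
For statistical experiments on the enrichment stage alone (family-wise error
under the null, recovery power), `generate_label_experiment` draws plant
sizes and Bernoulli labels without molecules, which makes hundreds of
replicates cheap; those simulations use 100 plants of 5–40 compounds with
ten enriched plants of 30 compounds at 90% active.

**What the benchmark does not show.** Synthetic actives are decorated
variants of a handful of scaffolds, far cleaner than real phytochemistry;
the near-perfect AUC on this benchmark demonstrates the machinery, not
real-world accuracy. Decoys are not property-matched to actives
(no DUD-E-style matching), inactive chemistry is eight chemotypes rather
than a continuum, and plant–compound annotations are complete, unlike real
databases where many plants have too few annotated compounds to be testable.

## Determinism and degenerate inputs

All randomness flows through `numpy.random.default_rng(seed)`; the same
config and seed reproduce byte-identical files. Unparseable structures are
skipped and counted in the log, never fatal. Empty panels and empty
libraries raise typed errors; an empty plant set yields an empty network and
a warning. Tables are UTF-8 TSV with floats at 12 significant digits, which
round-trips values to within half an ulp of the 12th digit.
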