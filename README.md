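# metabonet

Weighted co-expression network analysis for LC-MS metabolomics feature
tables.

Untargeted metabolomics experiments quantify hundreds to thousands of
molecular features (each an m/z × retention-time signal measured by its
peak area), most of them unidentified. Instead of testing features one at a
time, `metabonet` treats the feature table as a weighted network: features
with similar abundance profiles across samples form **modules**, each
summarised by one profile, and the handful of module summaries — not
thousands of individual peaks — is related to the phenotypic traits of the
experiment (diet, genotype, any numeric covariate). The same network also
ranks **hub metabolites** inside a module and transfers candidate
annotations from identified features to the unknown features most strongly
connected to them — a practical lever on the annotation bottleneck of
metabolomics.

## Method

For features *i*, *j* with Pearson correlation *cor(i,j)* across samples:

- **Signed adjacency** — `a_ij = ((1 + cor_ij)/2)^β`, so anti-correlated
  features get weight near 0. The soft threshold β is the lowest candidate
  for which the scale-free topology fit index `−sign(slope)·R²` of the
  log-log connectivity regression reaches 0.90.
- **Topological overlap** — `TOM_ij = (ℓ_ij + a_ij) / (min(k_i,k_j) + 1 −
  a_ij)` with `ℓ_ij = Σ_u a_iu a_uj` and connectivity `k_i = Σ_u a_iu`;
  `1 − TOM` is the clustering dissimilarity.
- **Modules** — average-linkage clustering of `1 − TOM`, a static tree cut
  with a minimum module size, then iterative enforcement of the membership
  rule: every member must keep `kME = cor(feature, ME) ≥ 0.7` with its
  module **eigenmetabolite** (ME, the first principal component of the
  module's standardized submatrix). Unassigned features form the grey
  module and are excluded downstream. Modules are named by decreasing size
  through the canonical palette (turquoise, blue, brown, ...).
- **Module–trait statistics** — `r = cor(ME, trait)` with the two-sided
  Student p-value `t = r√(n−2)/√(1−r²)`; metabolite significance
  `GS_i = cor(feature_i, trait)`; module significance `MS = mean |GS|` over
  members.
- **Hub graphs** — per-module graphs keep edges with `TOM > 0.13`; the hub
  is the member with the largest weighted degree; unknown features receive
  candidate annotations from their strongest identified neighbours.

A synthetic-data generator plants latent-factor modules with configurable
trait effects and log-normal peak-area scales, so every stage can be scored
against ground truth (adjusted Rand index, planted-hub recovery).

## Worked example

```python
from metabonet import (DetectionConfig, NetworkConfig, adjacency,
                       adjusted_rand_index, correlation_matrix,
                       detect_modules, eigenmetabolites,
                       module_trait_matrix, paper_shaped_fixture, preprocess,
                       topological_overlap)
from metabonet.io import PreprocessConfig

table, traits, truth = paper_shaped_fixture()   # 23 samples x 400 features
table = preprocess(table, PreprocessConfig(transform="log2"))
tom = topological_overlap(
    adjacency(correlation_matrix(table), NetworkConfig(power=4)))
labels = detect_modules(table, tom, DetectionConfig(min_cluster_size=6))
print(adjusted_rand_index(truth.labels, labels.labels))
# 0.871  -- the recovered partition closely matches the planted modules

me = eigenmetabolites(table, labels)
stats = module_trait_matrix(me, traits)
print(stats.correlation.round(2)["diet"].to_string())
# turquoise   -0.20
# blue         0.81    <- the planted diet-responsive module
# brown       -0.68    <- the planted negative diet module
# yellow       0.10
# green        0.04
# red         -0.12
# black        0.00
```

The diet-driven module tops both the eigenmetabolite–trait correlation
(0.81, p ≈ 2e-6 at n = 23) and the module significance, and within it the
most central members (high kME) are also the most diet-responsive (GS vs
kME r ≈ 0.70) — the behaviour expected when a trait acts on the module's
shared latent driver.

The `examples/` directory contains one short script per capability
(simulation + QC, power selection, module detection, trait statistics, hub
graphs and annotation transfer); each prints the numbers it computes with a
note on how to read them. A thin CLI wraps the same stages:
`metabonet simulate | qc | pick-power | detect | relate | hubs | evaluate |
run`.

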