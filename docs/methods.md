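# Methods

## Model and procedure

`metabonet` implements weighted co-expression network analysis for LC-MS
metabolomics feature tables. The input is a samples × features matrix of
peak areas with per-feature metadata (m/z, retention time, annotation) and
a samples × traits table (binary traits 0/1-encoded, so their Pearson
correlation with a profile is the point-biserial correlation).

The pipeline is: sample QC → preprocessing → correlation → signed
soft-threshold adjacency → topological overlap (TOM) → module detection →
eigenmetabolites → module–trait statistics → hub graphs and annotation
transfer. Every step is deterministic; randomness exists only in the
synthetic-data generator.

**Correlation.** Pearson by default; Spearman optional for heavy-tailed
peak areas. Zero-variance features are a hard error — they must be removed
in preprocessing (the pipeline drops them automatically).

**Signed adjacency.** `a_ij = ((1 + cor_ij)/2)^β` maps correlation −1 → 0,
0 → 2^−β, +1 → 1, preserving the sign structure that an unsigned `|cor|^β`
network discards. `β ≥ 1`; the default β = 4 is the value appropriate to a
signed metabolomics network of this density, and an automatic chooser is
provided: over candidate powers (1..20 by default) the **scale-free fit
index** is computed by binning connectivities `k_i = Σ_{j≠i} a_ij` into 10
equal-width bins, regressing log10(bin frequency) on log10(bin mean k) over
non-empty bins, and signing the R² by the negated slope so that rising
degree distributions can never qualify. The chosen power is the lowest
candidate whose fit index reaches the target (0.90); if none qualifies the
best-fitting candidate is returned with a warning flag, never silently.

**TOM.** `TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with
`ℓ_ij = Σ_{u≠i,j} a_iu a_uj`, computed as a single matrix product with the
diagonal zeroed. Because the signed adjacency is already non-negative no
separate signed-TOM bookkeeping is required. Entries are clipped to [0, 1]
and the diagonal set to 1; `1 − TOM` is the clustering dissimilarity.

## Module detection

Average-linkage hierarchical clustering on `1 − TOM`
(`scipy.cluster.hierarchy.linkage`). Assignment uses three primitives:

1. **Static cut**: the tree is cut at the `cut_quantile` quantile (default
   0.99) of its merge heights; flat clusters smaller than
   `min_cluster_size` (default 20) dissolve to grey.
2. **Membership filter**: iteratively, module eigenmetabolites and kME are
   recomputed and any member with own-module kME below `min_kme_to_stay`
   (default 0.7) moves to grey; modules shrinking below the minimum size
   dissolve. Convergence is an unchanged label vector, capped at 10 passes.
3. **Color naming**: final modules are renamed by decreasing size through
   the canonical palette, ties broken by smallest member feature ID, grey
   reserved for unassigned features and excluded from all downstream
   statistics.

A single static cut of an average-linkage tree tends to lump several
co-abundance blocks into one cluster, and the membership filter can then
keep only the block that dominates the cluster's first principal
component. `detect_modules` therefore applies the cut + size rule + filter
as an *extraction round* and repeats it on the still-grey remainder
(re-clustered on its TOM submatrix) until a round yields no new module
(≤ 10 rounds). Within a round, if the configured quantile yields no
surviving module the cut retries at descending quantiles
(0.95, 0.90, … 0.30) — lower cuts land in the height window where blocks
are still intact but not yet merged with background. This keeps each
primitive simple and auditable while recovering multiple planted modules
reliably; a dynamic tree-cut algorithm is deliberately not reproduced.
Optional merging of modules whose eigenmetabolite dissimilarity falls below
`merge_cut_height` (default 0.25) is available but off by default.

**Eigenmetabolites.** Per module, member profiles are z-scored across
samples (ddof = 1); the ME is the first left singular vector of that
matrix, rescaled to zero mean and unit variance, with its sign oriented so
it correlates non-negatively with the module's mean standardized profile —
this makes downstream trait correlations reproducible across linear-algebra
backends, where the SVD sign is arbitrary. Variance explained is the first
squared singular value over the total. A single-member module degenerates
to that member's standardized profile (variance explained 1, warning
logged).

## Trait statistics

Module–trait cells are Pearson correlations between MEs and traits with
two-sided Student p-values (`t = r√(n−2)/√(1−r²)`, n−2 df; |r| = 1 maps to
p = 0 exactly). No multiple-testing correction by default — the table
reports raw correlation tests — with Benjamini–Hochberg available by flag.
Metabolite significance GS is the signed feature–trait correlation; module
significance MS averages |GS| over members (the signed variant is exposed
for scatter plots). The eigenmetabolite network is the correlation matrix
over MEs plus any interposed trait vectors, clustered by average linkage on
`1 − cor` to expose meta-modules.

## Hub graphs and annotation transfer

A module graph keeps edges with TOM **strictly greater** than the threshold
(default 0.13); isolated nodes are retained. Hub ranking orders members by
weighted degree over those edges, ties broken by largest single incident
edge then feature ID, so the order is a deterministic total order; raw
intramodular connectivity (TOM row sums over the module, ignoring the
threshold) is reported as a secondary column. Unknown features (empty
annotation) receive their annotated neighbours ranked by descending edge
TOM, truncated to k; annotation never propagates from another unknown.
Graphs export to GraphML (node metadata + edge weights) or an edge TSV,
both round-tripping to ≥ 12 significant digits.

## Preprocessing defaults

`max_missing_fraction = 0.5`, `impute = half_minimum` (half the feature's
observed minimum — the standard stand-in for values below the detection
limit), `transform = none`. Empty cells and NA tokens are missing; a
literal 0 is a measured zero. Defaults mirror an analysis run directly on
exported peak areas; a log2 transform is recommended (and used throughout
the examples and tests) because peak areas are approximately log-normal and
correlations computed on the log scale are not attenuated by the
multiplicative noise. Sample QC clusters samples by average linkage on
Euclidean distance between per-feature z-scores; with a cut height,
singleton clusters above the cut are flagged as outliers and excluded by
the pipeline.

## Synthetic data

The generator emulates the structure of a small-cohort LC-MS study: a 2×2
diet × genotype design with 6/5/6/6 animals (23 samples) by default. Each
planted module m has a latent factor `f_m ~ N(0,1)` per sample, shifted by
a configurable effect (in factor-SD units) between the levels of a trait;
member feature i is `λ_i f_m + σ ε` with loadings λ drawn uniformly from
`loading_range` and noise σ = 0.5; background features are pure noise. The
signal maps to abundances as `exp(b_i + 0.5·signal)` with per-feature
baselines `b_i ~ N(12, 1.5²)` (natural-log units, peak areas ~ 1e4–1e7).
One global seed drives per-module substreams, so adding a module never
reshuffles earlier draws and a fixed seed reproduces the table bit for bit.

Defaults: `loading_range = (0.7, 0.95)` gives within-module correlations
≈ 0.7, the regime used for the recovery benchmark (5 modules of
60/50/40/30/20 features over 300 background, 24 samples). The 23-sample
*paper-shaped fixture* instead uses `loading_range = (0.4, 0.95)`, giving
modules hub-like and peripheral members; with a trait acting on the factor,
membership (kME) and trait response (|GS|) then correlate within the module
by construction — the signature of a trait-driven module. Its seven module
sizes (60/41/36/12/10/8/7 in a 400-feature table) scale down a realistic
size ladder; effects are diet +3 factor-SD on one mid-sized module, diet
−1.2 on another, genotype +1.5 and −1.0 on two more. For the 6/5/6/6
design an effect e yields a population factor–trait correlation
`e·sd(t)/√(e²·var(t)+1)` ≈ 0.83 at e = 3, so the strongest planted
association lands in the high-0.8s at n = 23.

What the generator does **not** emulate: chromatographic drift, batch
effects, heteroscedastic or censored missingness, isotope/adduct
redundancy, and non-linear feature dependencies. Passing recovery tests
therefore demonstrate correctness of the network machinery under the
latent-factor model, not performance guarantees on any real metabolome.

## Numerical choices and degenerate inputs

- Correlation matrices are symmetrized and clipped to [−1, 1]; adjacency
  and TOM are clipped to [0, 1] with unit diagonals.
- kME uses the same ddof = 1 standardization as the ME itself, and is
  clipped to [−1, 1].
- The scale-free fit skips empty bins and bins with non-positive mean
  connectivity; fewer than two usable bins, or an all-equal degree
  distribution, is an error rather than a fabricated fit.
- Detection on data with no structure legitimately returns all-grey; the
  pipeline logs it and skips the downstream stages rather than failing.
- The full analysis path is deterministic, so pipeline reruns with the same
  configuration produce byte-identical tables (figures are exempt).

## Known limitations

- The static-cut extraction scheme, while robust on block-structured data,
  is not the dynamic-hybrid tree cut; branch-shape-sensitive splits of
  nested modules are out of scope.
- Trait association is correlation-only; no covariate adjustment.
- Annotation transfer is purely co-expression evidence; it suggests
  candidate neighbours, not identifications, and records m/z and RT
  metadata without attempting mass-based matching.
- Dense matrices bound the practical scale to ~2×10⁴ features; the
  metabolomics regime (10²–10⁴) fits comfortably (23 × 4111 runs end to
  end in well under a minute on one CPU).
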