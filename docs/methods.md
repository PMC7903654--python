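# Methods

This note records the statistical model, the numerical choices, and the
known limitations of `diffconet`, in the package's own terms.

## Harmonization

Microarray-style inputs arrive as probe × sample matrices from several
cohorts ("batches"). Three steps make them comparable:

- **Probe collapsing** (`collapse_probes`): when several probes map to one
  gene, the probe with the highest mean intensity across samples is kept
  (`mode="max_mean"`, ties broken by probe identifier; `mode="mean"`
  averages instead). Unmapped probes are dropped.
- **Z-score standardization** (`zscore_standardize`): each gene is centered
  and scaled to unit variance (ddof = 1) *within each batch*, removing
  additive and multiplicative batch effects per gene. Constant genes
  become all-zero with a warning; a batch with a single sample is an error
  because its variance is undefined.
- **Merging** (`merge_datasets`): datasets are joined on the intersection
  of their gene sets (order of the first dataset), concatenating samples.
  Duplicate sample identifiers are rejected.

Standardization means downstream "fold changes" are differences of
standardized group means, not literal log-ratios; the DEG table calls this
column `effect`.

## Differential expression

Per gene, Welch's unequal-variance t-test compares disease vs control
samples (two-sided). A gene is a DEG when raw p < 0.05 and |effect| >
threshold (default 0: any nonzero difference in the called direction).
Benjamini–Hochberg adjusted p-values are reported but do not gate the
call — the gate mirrors the common raw-p screening practice in this
analysis style; switch to FDR gating upstream if desired by filtering on
`p_adj`. Degenerate genes (zero variance in both groups) get p = 1 when
the means agree and p = 0 otherwise.

## Co-expression networks

For one (tissue, condition) slice, pairwise Pearson correlation is
computed over that condition's samples (≥ 3 required; constant genes give
undefined correlation and are excluded from edge formation). An edge
joins a pair when |r| ≥ 0.5 (`mode="abs"`, the default) or r ≥ 0.5
(`mode="positive"`). The 0.5 default is the conventional "moderate
correlation" cut for thresholded co-expression networks; it is a
configuration knob, not a fitted value. Genes with no qualifying partner
are excluded from the node set but counted against the universe as
unconnected.

Topology metrics, with conventions chosen once and used everywhere:

- **Mean local clustering**: C_i = 2·links(N_i) / (k_i (k_i − 1)), with
  C_i = 0 for degree < 2; network value is the mean over nodes
  (networkx `average_clustering`).
- **Density**: 2E / (n (n − 1)) over connected nodes.
- **Degree centralization** (Freeman): Σ(k_max − k_i) / ((n − 1)(n − 2));
  1 for a star, 0 for a regular graph, defined as 0 for n < 3.
- **Degree distribution**: histogram plus a Gaussian KDE (Silverman
  bandwidth, 512-point grid over [0, k_max + 3 bandwidths]); the sample
  variance (ddof = 1) of the connected nodes' degrees summarizes spread.

## Connectivity comparison

Per gene in the intersection of the two condition universes, the degree
difference δ = k_disease − k_normal (0 for isolates) is classified as
gain / loss / unchanged. The paired Wilcoxon signed-rank test is applied
to the δ vector: zeros are dropped (Wilcoxon's rule; Pratt's zero handling
is available behind `zero_method="pratt"`, and an unpaired Mann–Whitney
rank-sum behind `paired=False`), |δ| are midranked under ties, and W is
the positive-rank sum. For ≤ 25 effective pairs, the null distribution of
W is computed exactly by dynamic programming over the 2^n sign
assignments, with midranks doubled to integers so ties are handled without
approximation; beyond that, the normal approximation with tie-corrected
variance n(n+1)(2n+1)/24 − Σ(t³−t)/48 and a 0.5 continuity correction is
used. Two tissues' gain/loss summaries are compared as ratios.

### Known limitation: degree differences are not independent

The signed-rank test assumes independent pairs. Per-gene degree
differences violate this structurally: an edge present in one network and
absent in the other changes the degree of **both** endpoints, so the δ's
are positively cross-correlated. Summing the pairwise covariances shows
the variance of any sign statistic over genes is inflated by at least ~2×
relative to independence, and planted module structure makes it far worse
(all within-module correlations co-move with the module's latent factor,
so a module contributes roughly one independent observation, not ~190).
Measured under a null generator with identical conditions, the nominal
α = 0.05 test rejects in ≈ 60% of replicates. This is a property of
applying the signed-rank test to network degrees — the test itself is
verified exactly calibrated on independent inputs by enumeration — and
the acceptance suite keeps a failing calibration test as documentation
rather than hiding it. Connectivity p-values on real data should be read
as descriptive strength-of-shift scores, not calibrated error rates.

## Pathway enrichment and crosstalk

Over-representation of the DEG list in each GMT gene set is tested
one-sided: p = P(X ≥ k) for X hypergeometric with the post-harmonization
gene universe as background, pathways intersected with the universe first
and skipped when disjoint. BH adjustment is computed across tested
pathways; the `is_enriched` flag gates on raw p by default
(`gate="raw"`, mirroring screening practice) with `gate="fdr"` available.
Direction-resolved runs (`up` / `down`) subset the DEG table by call
direction.

Enriched pathways and their member DEGs form a bipartite network;
node degree counts membership incidences (protein-interaction edges are
carried through and can optionally count toward gene degree via
`count_interactions_in_degree`). The top-10 nodes per side are ranked by
degree (ties by name), and genes belonging to ≥ 2 enriched pathways are
reported as crosstalk genes.

## Candidate-gene evaluation

Each evaluated gene gets, per tissue: the Welch p (BH-corrected within
the evaluated family per tissue) and the ROC AUC with the gene's
standardized expression as the classifier score,
AUC = U / (n₁ n₂) via midranks (ties count half). `auc_oriented`
= max(AUC, 1 − AUC) scores discrimination regardless of direction.

## Synthetic generator

Expression for gene g in module m is x = √ρ · f_m + √(1 − ρ) · ε with
f_m, ε independent standard normal per sample, giving pairwise correlation
exactly ρ inside the module and 0 elsewhere — a closed-form oracle for
network recovery. Disease samples redraw rewired modules at
`rho_disease`; DE genes get a ±`de_shift` mean offset in disease (a
configurable fraction shifted down); per-(batch, gene) offsets ~
N(0, batch_sd) emulate batch effects; two tissues share a stated fraction
of DE genes. The documented **recovery preset** is 400 genes, 10 modules
of 20, ρ = 0.81 normal vs 0.25 in the 5 rewired modules, 25% DE genes
with unit shift, 60 samples per group, 3 batches. At the 0.5 edge
threshold with n = 60 these choices put intact-module edges at
probability ≈ 1 and rewired-module edges near 0, so disease networks are
reliably sparser with losses dominating — the package's qualitative core,
asserted over seeds in the acceptance suite.

Pathway fixtures draw `overlap_fraction` of each enrichment-positive
pathway's members from **one** tissue's planted DE pool (default: the
first tissue) and the rest from background, disjointly across pathways
except for deliberately planted multi-pathway crosstalk genes; negative
pathways are background-only. Enrichment recovery is therefore planted —
and asserted — in the seeding tissue. Interaction edges are Bernoulli
per pair with separate within-module and background densities. Pipeline
runs persist `truth.json` and `pathway_truth.json` so recovery can be
verified from artifacts alone.

Problem sizes (400 genes, 60 samples/group, 16 pathways of ~15) are
package choices tuned for seconds-scale runs on one CPU while keeping all
planted contrasts far from decision boundaries; they are not estimates of
any particular cohort.

## Determinism

All randomness flows through `numpy.random.default_rng(seed)`. The
pipeline report is serialized with sorted keys and non-finite values
mapped to null, and the config hash excludes the output directory, so an
identical configuration and seed reproduce `report.json` byte for byte.
TSV artifacts are written at `%.17g` and read with round-trip float
parsing so every artifact re-reads to its in-memory object exactly.
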