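# diffconet

Differential co-expression network analysis for two-condition,
two-tissue gene expression studies.

Many disease transcriptome studies find few large per-gene expression
changes but substantial rewiring of *co-expression*: pairs of genes that
track each other tightly in healthy tissue decouple in disease. `diffconet`
implements that analysis end to end:

1. **Harmonize** expression matrices across array batches: collapse probes
   to genes (max-mean rule), z-score each gene within each batch, and merge
   cohorts on their common gene set.
2. **Call DEGs** per tissue with Welch's t-test on the standardized values
   (the effect size is the disease-minus-control mean difference in
   standardized units), with BH-FDR reported alongside the raw-p call.
3. **Build co-expression networks** per (tissue, condition): genes are
   nodes, and an edge joins any pair with |Pearson r| ≥ 0.5 across that
   condition's samples. Topology is summarized by node/edge counts, mean
   local clustering, density, Freeman degree centralization, and a degree
   histogram with a Gaussian-kernel density curve.
4. **Compare connectivity**: per-gene degree difference between the disease
   and normal networks (gain / loss / unchanged), tested with a Wilcoxon
   signed-rank test whose null distribution is computed exactly (ties
   included) up to 25 effective pairs; tissues are compared by gain and
   loss ratios.
5. **Enrich pathways**: one-sided Fisher (hypergeometric) test of the DEG
   list against GMT gene sets, with BH adjustment.
6. **Assemble the pathway–gene crosstalk network**: a bipartite graph of
   enriched pathways and their member DEGs (optionally decorated with
   protein-interaction edges), ranked by degree; genes in ≥ 2 enriched
   pathways are the crosstalk genes.
7. **Evaluate candidate genes**: per-tissue Welch p (BH-corrected within
   the candidate family) and single-gene ROC AUC (Mann–Whitney
   concordance), with `auc_oriented = max(AUC, 1 − AUC)`.

Because the public cohorts this style of analysis is usually run on require
bulk downloads, the package ships a **seeded synthetic generator**
(`diffconet.synthetic_data`) that plants correlation modules through a
latent-factor model (pairwise correlation exactly ρ inside a module),
module rewiring in disease, per-tissue differential expression with a
shared core, batch offsets, GMT pathway fixtures with known
enrichment-positive sets and planted crosstalk genes, and an interaction
edge list — all with machine-readable ground truth for recovery testing.

## Quick start

Run the full pipeline on the documented synthetic preset:

```bash
diffconet run --out out --seed 1
```

or from Python:

```python
from diffconet import PipelineConfig, recovery_preset, run_pipeline

report = run_pipeline(
    PipelineConfig(outdir="out", synth=recovery_preset(), seed=1)
)
```

With seed 1 this writes `out/report.json` containing, among other things:

- 117 DEGs in tissue ACC and 105 in PFC (of 400 genes; 52 shared),
- ACC networks with 260 edges (normal) vs 150 (disease); PFC 166 vs 75,
- connectivity losses dominating gains (ACC: 30 losses, 0 gains;
  Wilcoxon p ≈ 1.5e−06),
- 8 of 16 pathways enriched in ACC — exactly the planted positives,
- 3 crosstalk genes — exactly the planted multi-pathway genes,
- top-gene oriented AUC averaging ≈ 0.71 across both tissues.

Identical config + seed reproduces `report.json` byte for byte.

Real data goes in as TSV: one expression matrix (genes × samples) and one
metadata table (`sample_id, condition, tissue, dataset`) per cohort, plus
optional probe-map, GMT, and interaction files:

```bash
diffconet run --config analysis.yaml
```

where `analysis.yaml` holds a `PipelineConfig` document (see
`PipelineConfig.from_yaml`). Individual stages are also exposed as
subcommands (`simulate`, `harmonize`, `deg`, `net`, `diffnet`, `enrich`,
`crosstalk`, `evaluate`) for ad-hoc use.

## Testing

`pytest` runs unit tests per module plus `tests/test_acceptance.py`, one
test per acceptance criterion: graph-metric and statistical oracles
(brute-force enumeration, log-gamma hypergeometric tails, sign-assignment
Wilcoxon nulls, pairwise-concordance AUC), type-I calibration under null
generators, parameter recovery at the documented preset, end-to-end
recovery of planted pathway structure, and determinism / artifact
round-trips.

One acceptance test fails by design:
`test_criterion_3b_wilcoxon_rejection_calibration` documents that the
signed-rank test applied to per-gene degree differences is
anticonservative — every edge difference changes the degree of *both*
endpoints, and module structure correlates the differences further, so the
test's independence assumption is structurally violated on network degree
data. See `docs/methods.md` for the analysis; the implementation itself is
verified exactly calibrated on independent inputs by the enumeration
oracle.
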