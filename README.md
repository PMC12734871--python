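# phytofp

Untargeted LC–MS/MS fingerprinting of anthraquinone-containing herbal drugs
(Cascara, Frangula, Rhubarb, Senna): feature-table screening with MSI
confidence levels, graph-neural-network classification of annotated
metabolites into the natural-product hierarchy, expert-concordance curation,
and cross-species comparative statistics — exercised end-to-end on synthetic
data with known ground truth.

## What it does

Herbal drugs rich in hydroxyanthracene derivatives (HADs) are routinely
profiled by UPLC–HRMS/MS, with features processed in vendor software and
annotated against spectral databases. `phytofp` implements the downstream
analysis a comparative phytochemistry study needs:

1. **Screening** (`phytofp.screening`) — five pure-predicate filters on
   vendor-style feature tables: database confirmation in ≥ 1 of five sources
   (mzCloud, mzVault, Metabolika, ChemSpider, MassList), mass accuracy
   |Δm/m| ≤ 3 ppm against the [M+H]⁺/[M−H]⁻ theoretical m/z, retention time
   in 5–50 min (extensible to 0–120), minimum peak area, and MS2
   availability. MSI levels follow the Metabolomics Standards Initiative:
   1 = standard-confirmed with MS2, 2 = accurate mass + MS2 database match,
   3 = database hit without MS2, 4 = unannotated.
2. **Classification** (`phytofp.molgraph`, `phytofp.gin`,
   `phytofp.np_classifier`) — molecules are converted from SMILES to
   heavy-atom graphs (atom type, degree, hybridization, formal charge,
   aromaticity; bond type and conjugation) and classified by per-level Graph
   Isomorphism Networks (pathway → superclass → class), evaluated with
   stratified 10-fold cross-validation (macro-F1, accuracy). The GIN layer
   computes `h' = MLP(h + Σ_neighbours h + Σ_incident W_e e)` with sum
   pooling, so predictions are invariant to atom input order. Confidence is
   the per-level maximum softmax probability; weak or hierarchy-inconsistent
   assignments are queued for expert review.
3. **Curation** (`phytofp.curation`) — concordance of predicted vs expert
   superclass labels, with raw counts reported beside the percentage and
   both denominator conventions for unlabelled compounds.
4. **Comparison** (`phytofp.comparative`) — Venn membership regions over
   species compound sets (2^k − 1 regions by normalized compound name),
   superclass × species distribution tables, the compounds × replicates
   abundance matrix, PCA on the autoscaled matrix, hierarchical clustering
   under Euclidean distance, and the superclass × replicate heatmap matrix.
5. **Synthetic data** (`phytofp.synthetic`) — everything above is testable
   against planted truth: feature tables with per-rule violation rates,
   scaffold-labelled molecule sets (flavone, flavonol, anthraquinone,
   cinnamate, stilbene templates with random substituents), and four-species
   profiles realizing an exact Venn membership design with lognormal
   per-species intensities.

## Worked example

```bash
phytofp run --seed 1 --outdir runs/demo
```

runs the full synthetic study (generate → screen → classify → curate →
compare) and prints the per-stage manifest. With the default generator the
four species carry 93, 83, 83 and 51 compounds; screening removes exactly
the planted background features (40 per replicate, 120 per species), and
the comparison stage reports:

```
"compare": {
  "n_superclasses": 4,
  "pc1_pct": 41.789,
  "pc2_pct": 32.812,
  "union": 253,
  "venn_core": 4
},
"profiles": {
  "Cascara": 93, "Frangula": 83, "Rhubarb": 83, "Senna": 51
}
```

meaning: 253 distinct compounds across the four species, exactly 4 shared
by all (the planted core), and the first two principal components of the
autoscaled 253 × 12 abundance matrix explain 41.8% + 32.8% of the variance.
Per-species outputs land in `runs/demo/` as CSVs (`screened.csv`,
`predictions.csv`, `concordance.csv`, `venn.csv`, `distribution.csv`,
`pca_scores.csv`, `pca_variance.csv`, `hca_merges.csv`,
`heatmap_counts.csv`) plus `manifest.json`; add `--figures` for SVG plots.

The same stages are available individually (`phytofp generate`, `screen`,
`train`, `classify`, `curate`, `compare`) and as library calls; see the
module docstrings.

## Scope

The package consumes vendor *export* tables; peak picking, alignment and
spectral matching (and raw mzML parsing) are upstream and out of scope, as
are supervised multivariate models and univariate hypothesis testing.
See `docs/methods.md` for the modelling choices and their rationale.
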