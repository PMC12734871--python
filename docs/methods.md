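# Methods

## Screening model

A detected feature is one row of a vendor compound export: name, molecular
formula, precursor m/z (Da), calculated neutral monoisotopic mass (Da),
retention time (min), maximum peak area (instrument counts), ionization
polarity, database-match evidence and MS2 availability. Screening applies
five independent predicates; a record survives iff all hold:

| rule | predicate | default |
|------|-----------|---------|
| db   | matched in ≥ 1 of the five annotation sources | required |
| ppm  | \|(obs − theo)/theo\| · 10⁶ ≤ tolerance | 3 ppm |
| rt   | elution inside the window | 5–50 min (optional 0–120) |
| area | peak area ≥ threshold | 1.0 × 10⁵ counts |
| ms2  | fragmentation spectrum present | required |

The theoretical m/z is derived from the neutral mass assuming protonation /
deprotonation only ([M+H]⁺, [M−H]⁻; proton mass 1.007276 Da); other adducts
are out of scope. Because each rule is a pure predicate, the surviving set
is independent of evaluation order; failure *attribution* uses the fixed
order db, ppm, rt, area, ms2 (a record failing several rules is counted
under the first), which makes reports deterministic and makes the counts
conserve: passed + Σ per-rule failures + per-record errors = input.

The area threshold deserves a note: thresholds quoted as "10⁻⁵" circulate
in the application literature but are physically implausible for Orbitrap
peak areas (every feature would pass). The default is 10⁵ counts — a value
that actually separates low-intensity background — and the threshold is
fully configurable for users who want a different gate.

MSI levels are assigned monotonically in evidence: standards-list membership
with MS2 → 1; MS2 + database hit → 2; database hit without MS2 → 3;
otherwise 4. The split of the "3/4" tier follows the evidence ordering
(a database hit is strictly more evidence than none).

## Molecular graphs

SMILES are parsed and sanitized with RDKit; hydrogens stay implicit (the
standard choice for graph-level property prediction — no hydrogen-specific
features exist in the featurization). Stereochemistry is ignored: none of
the node/edge features depend on it, and the scaffold-level classification
task is stereochemistry-blind. Nodes carry element, degree, hybridization
(sp/sp2/sp3/other), formal charge and aromaticity; edges carry bond type
(single/double/triple/aromatic) and conjugation. Categorical features are
one-hot encoded against a vocabulary fitted on the training molecules;
unseen elements or charges fall into an `other` bucket with a warning, so
inference never fails on exotic atoms. The vocabulary is persisted with
every trained model.

## The GIN classifier

One network per hierarchy level (pathway, superclass, class), trained
independently; hierarchical consistency of a decoded prediction (class →
superclass → pathway parent chain) is checked afterwards against the
ontology, and an optional strict mode masks class probabilities to children
of the predicted superclass instead. Decoding takes the per-level argmax
(ties broken by label order); confidence is the maximum softmax
probability at that level.

Layer update: `h'_v = MLP((1+ε)·h_v + Σ_{u∈N(v)} h_u + Σ_{e∋v} W_e x_e)`
with ε = 0 and a two-layer ReLU MLP; readout is sum pooling over atoms
followed by a linear softmax classifier. Sum aggregation and sum pooling
make the network exactly invariant to atom input order (inference runs in
float64; the invariance holds to ~1e-15 in practice) and give GIN-class
discriminative power (Weisfeiler–Lehman equivalence).

Defaults: 5 layers, hidden width 64, dropout 0.2 on MLP hidden activations,
Adam at 10⁻³, 100 epochs of full-batch training, weight init N(0, 0.1²) —
conventional values for small-molecule graph classification, all exposed in
`GinConfig`. Training runs a fixed epoch budget rather than early stopping:
at desk scale (hundreds of molecules) a nested validation split would be
noisy, the loss plateaus well before 100 epochs on scaffold-level tasks,
and a fixed budget keeps cross-validation folds exactly comparable and the
whole procedure deterministic. Training arithmetic is float32 (bandwidth-
bound full-batch updates); a single integer seed drives fold assignment,
weight initialization and dropout, so a rerun reproduces reports
bit-for-bit on the same platform.

Evaluation is stratified 10-fold cross-validation with macro-averaged F1
and accuracy (mean ± sd over folds), then a final refit on all data. The
fold builder deals each class's shuffled members round-robin from a
rotating offset, so per-fold per-class counts differ by at most one and
classes smaller than k still spread across folds (scikit-learn's
StratifiedKFold rejects that case, hence the in-package implementation).
Classes with fewer than 10 examples can be merged into a per-superclass
`other` bucket before class-level training. Macro-F1 averages per-class F1
over classes observed in truth or prediction.

## Curation

A prediction is confirmed when its superclass equals the expert label after
whitespace/case normalization (the superclass vocabulary is closed; no
synonym resolution). Published concordance percentages are ambiguous about
whether expert-unlabelled compounds count in the denominator, so the report
always carries raw counts beside the percentage and supports both
conventions (default: unlabelled compounds stay in the denominator as
unconfirmed). The curation queue orders flagged predictions by their
weakest per-level confidence, ascending — the workflow where high-confidence
assignments are accepted by default and only flagged cases are reviewed.

## Cross-species comparison

Compound identity across species is the normalized name (case, whitespace,
punctuation folded). Formulas are retained for auditing but never used as
the key: positional isomers (e.g. aloin A/B) share a formula and must stay
distinct. A compound belongs to a species if it passed screening in at
least one replicate; when a compound appears in both ESI polarities, the
higher-area mode's records are kept.

* **Venn regions**: the union of compounds is partitioned into the 2^k − 1
  membership patterns; counts plus member lists are reported.
* **Distribution table**: superclass × species counts with per-species
  percentage columns, rows ordered by total count.
* **Abundance matrix**: union compounds × (species × replicates), zero when
  a compound was not detected in a sample. Zeros are treated as informative
  absence, not missingness — no imputation.
* **PCA**: per-compound autoscaling (z-score) by default, matching standard
  metabolomics practice; pareto and no scaling available. Constant rows are
  dropped (they carry no information and would divide by zero) and
  reported. Computation is SVD of the centered sample matrix; explained
  variance percentages are eigenvalue shares, with component signs fixed by
  making the largest-magnitude loading positive.
* **HCA**: Euclidean distance on sample columns; average linkage by default
  (ward and complete available), delegated to scipy's linkage with its
  deterministic tie-breaking.
* **Heatmap matrix**: superclass × replicate counts of detected compounds
  (area > 0), raw and unnormalized, with row/column orders from
  average-linkage Euclidean clustering.

## Synthetic data generator

The generator emulates the *structure* of a four-species comparative study
so that every downstream count is predictable from a ledger without running
the pipeline:

* **Feature tables**: one row per compound × replicate with m/z computed
  from the molecular structure's exact mass plus planted ppm noise
  (clean rows within ±2 ppm), retention times inside the window, lognormal
  areas, random database-hit subsets. Violations are planted at per-rule
  rates and are **mutually exclusive per row** (a categorical draw per
  row), so first-fail attribution is unambiguous and ledger arithmetic is
  exact. In the study-shaped tables, member compounds are guaranteed clean
  and each replicate adds a fixed number of decoy features that each
  violate exactly one rule, so screening recovers the planted membership
  design exactly.
* **Molecules**: valid SMILES built by random substitution (H, hydroxyl,
  methoxy, methyl, hydroxymethyl, O-glycosyl) on flavone, flavonol,
  anthraquinone, cinnamate and stilbene templates — the dominant
  superclasses of HAD-containing plants — with uniqueness enforced on
  canonical SMILES. Family labels give a three-level hierarchy that a graph
  classifier can learn at desk scale.
* **Species profiles**: the default membership design reproduces the
  four-herbal-drug study's sharing structure exactly (species totals
  93/83/83/51; a 4-compound core; 21 compounds shared by the two
  Rhamnaceae barks, 10 of them exclusive to the pair; 13 shared by Senna
  and Rhubarb, 5 exclusive). Intensities are lognormal: a per-compound base
  level (sd 0.8 log units) plus a per-species log shift (default +1.2,
  +0.6, 0.0, −1.2) plus replicate noise (sd 0.15), with ionization polarity
  drawn once per compound (it is a property of the molecule, not the
  injection).

What the generator does *not* emulate: chromatographic peak shapes, isotope
patterns, adducts beyond [M±H], retention-order chemistry, correlated
co-elution, or annotation errors. Passing tests therefore demonstrate that
the analysis machinery is correct on data with the study's combinatorial
and intensity structure — not that annotation of real spectra is accurate.

One geometric consequence worth knowing: after autoscaling, every feature
contributes unit variance, so the PCA eigenstructure of a
membership-dominated design depends only on the region counts. With four
species carrying large exclusive sets of similar size, between-species
variance spreads over three comparable components (PC1 + PC2 ≈ 75% on the
default design). Strongly anisotropic variance splits like 87% + 11% arise
when intensity gradients, not membership, dominate — the generator
produces that regime when compounds are shared and species differ mainly
in log intensity (see the mean-shift test), but it is not derivable from
the default membership counts alone.

## Numerical and determinism choices

* All randomness flows from one integer seed per entry point; derived
  seeds stay below 2³¹.
* Feature-table round-trips write floats with `repr`, so read∘write is the
  identity to the last bit.
* Screening ppm arithmetic is float64 and verified against an
  arbitrary-precision Decimal oracle.
* PCA explained variances are validated against an independent
  eigendecomposition and scikit-learn; HCA against a brute-force
  agglomeration oracle.
* Graph parsing is cross-checked against Open Babel as a second,
  independent SMILES implementation.

## Problem sizes

Defaults are desk-scale: 253 union compounds across 4 species × 3
replicates, 300 training molecules per classifier task, 1000-row screening
tables, 10-fold cross-validation. A full synthetic pipeline run completes
in well under a minute without cross-validation; cross-validating one
level adds roughly a minute per level.

## Known limitations

* Adducts other than [M±H] and multiply charged species are not modelled.
* Confidence is the raw softmax maximum; no calibration is applied.
* The hierarchical models are trained independently per level; consistency
  is audited, not enforced (except in the optional strict decoding mode).
* Compound identity is name-based; two species annotating the same
  structure under different names would not be merged.
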