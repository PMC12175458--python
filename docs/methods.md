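# Methods

This note documents the models and procedures implemented in `actinomet`,
the parameters that matter, the design of the synthetic-data generator, and
the package's known limitations.

## Feature-table cleanup

Input feature tables are MZmine-style aligned peak lists (feature id, m/z,
retention time, per-sample intensities) with m/z restricted to the
full-scan acquisition window 100–1500 Da. Sample roles (isolate group,
`blank`, `medium`, `qc`) travel in a `role` row of the CSV itself, so a
table is self-describing. Missing values are encoded as intensity 0.

Two per-feature predicates clean the table:

* **Blank rule** (`blank_threshold`, default 1×10⁴ counts): a feature is
  removed when its intensity in any solvent blank is *strictly greater*
  than the threshold; a blank intensity of exactly 1×10⁴ is kept. This
  boundary reads the rule literally ("higher than").
* **Medium rule** (`media_fold`, default 20): a feature is kept iff its
  best biological intensity is at least `media_fold` times its best medium
  intensity (inclusive at exactly 20×). Features entirely absent from the
  medium are always kept.

Replicate blanks/media/samples are aggregated by **maximum** — the
conservative choice, since a feature that is loud in even one blank
injection is suspect. The rules are pure per-feature predicates on the
original rows, hence idempotent and order-independent; the pipeline applies
blank-then-medium. Mode merging row-concatenates the two cleaned tables
after asserting identical sample sets, prefixing ids `P_`/`N_`.

### NMR trimming and binning

¹H spectra in DMSO-d₆ are prepared for the same chemometric models by
zeroing solvent windows and integrating fixed-width bins. Defaults: bin
width 0.04 ppm; exclusions 2.47–2.53 ppm (residual DMSO quintet) and
3.28–3.40 ppm (water). The window widths are this package's convention —
the processing they emulate names the peaks but not the widths. Binning
uses `ceil(span / width)` bins with a 1e-9 epsilon guard against
floating-point jitter at bin boundaries.

## Exact-mass dereplication

Molecular formulas (Hill notation, no parentheses/isotopes) are parsed to
element counts and summed over IUPAC monoisotopic masses (carbon exactly
12), via the NIST table bundled with pyteomics. Adducts are singly charged:
[M+H]⁺ / [M−H]⁻ (proton 1.007276 Da) and optionally [M+Na]⁺ (22.989218 Da,
sodium minus one electron). The mass error is signed and computed against
the theoretical mass: ppm = (obs − theo)/theo × 10⁶; the default window is
5 ppm, inclusive. Hits per feature are sorted by |ppm| with ties broken by
library order then compound name, for reproducibility. Features without a
hit are reported as "no hits" — in a discovery campaign these are the
interesting ones.

The bundled reference library carries two transcription quirks worth
knowing: the printed pairings m/z 138.0807 ↔ C₁₆H₃₃N₃O₉ (sorbistin A2) and
m/z 370.1890 ↔ C₂₁H₂₆N₂O₄ (antibiotic C 13648) are internally inconsistent
(the formulas imply [M+H]⁺ ≈ 412.23 and 371.20). The package always works
from the formula-derived mass; the synthetic generator therefore plants
those compounds at their theoretical adduct m/z, not at the printed ion.

## Chemometrics

All models operate on a samples × features matrix after **Pareto scaling**:
centre each column, divide by the square root of its standard deviation
(ddof = 1). Zero-variance columns cannot be scaled and are dropped with a
warning. Pareto scaling is the field's compromise for intensity data:
unit-variance scaling amplifies noise features, no scaling lets the most
abundant ions dominate.

**PCA** is computed by SVD of the scaled matrix; r²x per component is
s_a²/‖X‖². The **Hotelling T² ellipse** at level α uses the critical value
A(n² − 1)/(n(n − A)) · F₁₋α(A, n − A) over the first two score vectors;
ellipse half-axes are √(crit · var(t_a)). Samples beyond the critical T²
are outliers. Component signs follow a fixed convention (the
largest-|loading| coordinate of each component is positive) so score plots
are reproducible run to run.

**PLS-DA** one-hot encodes class labels (centred dummy matrix, one column
per class) and extracts components by NIPALS (convergence Δt < 1e-10 or 500
iterations) with deflation of both blocks. R²Y(cum) = 1 − SS(E_Y)/SS(Y).
**Q²(cum)** = 1 − PRESS/SS(Y) with PRESS pooled over venetian-blind K-fold
cross-validation (default 7 folds): fold assignment cycles over the sample
order, Y is re-centred on each training fold, and X keeps its global
scaling (the small leakage this admits is the usual fast approximation).
Every training fold must retain every class, otherwise a stratification
error is raised. With 8 classes × 3 replicates and 7 folds it is not
possible to keep a group's replicates in a single fold without training
folds losing whole classes, so per-observation blinds are the default; a
`fold_groups` argument restores replicate-grouped folds for designs that
allow it. `n_comp="auto"` adds components while Q² improves by > 0.01.

**OPLS-DA** follows the orthogonal-projections scheme: the predictive
weight w comes from one NIPALS component of (X, Y); each orthogonal
component is the part of the X-loading orthogonal to w, removed from X by
deflation before the single predictive component is extracted. With
`n_orth = 0` the model coincides exactly with one-component PLS-DA; the
default is one orthogonal component. Predictive and orthogonal scores are
orthogonal by construction (verified to 1e-8 in tests). The **S-plot**
reports, per feature, p = cov(t_pred, x_j) and p(corr) = corr(t_pred, x_j)
against the *original* scaled matrix; discriminatory, reliable markers sit
in its extreme corners (top decile of |p(corr)| is the package's working
definition).

**VIP** uses VIP_j = √(p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a) with
SSY_a = (tᵀt)(cᵀc); the identity Σ VIP² = p holds algebraically and is
asserted to 1e-8. Features above 1 contribute more than average.

**Random forest** ranking wraps scikit-learn's
`RandomForestClassifier` (impurity-decrease importances, 300 trees,
seeded, single-threaded) and returns the top-k (default 15) — an
orthogonal, non-linear check on the latent-variable models.

The permutation null (`permutation_q2`) refits PLS-DA under shuffled
labels; a sound model collapses to Q² ≤ 0 on average.

## Bioactivity association

* Zone positivity is inclusive at 12 mm; `NA` zones mean "no inhibition
  observed" and are treated as inactive, never imputed.
* IC₅₀ comes from a four-parameter logistic fit
  v(c) = bottom + (top − bottom)/(1 + (c/e)^h) over the tested ladder
  (128, 32, 8, 2, 0.5 µg/mL); the reported IC₅₀ is the concentration where
  the *fitted* viability crosses 0.5 absolute. If the curve never crosses
  0.5 inside the tested range the result is "not reached" (NaN, printed
  NA). Clearly non-monotone series warn but are still fitted.
* Replicate IC₅₀ sets are compared by a two-sided unpaired Student t-test
  (equal variances); two zero-variance samples are an error.
* The correlation stage computes Pearson r and two-sided p per
  (feature, activity readout) on **group-mean** intensities (replicates
  averaged, since bioactivity is a per-group readout). The
  "significantly different" prefilter is pluggable; the default is a
  per-feature one-way ANOVA across isolate groups at p < 0.05. No
  multiple-testing correction is applied to the correlation p-values by
  default (a raw α mask, as in the workflow this mirrors); pass the
  p-matrix to any correction of choice if desired.
* Cytotoxic potency may optionally be encoded as 1/IC₅₀ by the caller;
  the default reports correlations against IC₅₀ itself, so a *negative* r
  with IC₅₀ means "more metabolite, more potent".

## The synthetic-data generator

`SynthConfig` defaults define the emulated study conditions: 8 isolate
groups (labelled 6, 10, 12, 35, 42, 43, 45, 48) × 3 replicates, 2 blanks,
3 medium controls, 4 pooled QCs, 250 features per ionization mode,
log-normal multiplicative noise of σ = 0.1 decades, 2% random dropout on
unstructured features, m/z in 100–1500 Da.

Planted structure:

* **Background** (60 features): ~1×10⁵ in blanks, medium and samples —
  removed by the blank rule by construction.
* **Marker clusters** (7 features each): cluster 1 belongs to groups
  6/35/45, cluster 2 to 12/42/43/48, cluster 3 is private to the outlier
  group 10. Member-group intensity ~1×10⁵ against a 1×10³ baseline;
  medium level is set to member-level/(2 × `marker_fold`)
  (`marker_fold` = 50 ≥ the 20× rule), so markers always survive the
  filters. Outlier privates sit at 10× typical marker intensity, which
  reliably pushes group 10 outside the 95% Hotelling ellipse.
* **Planted annotations**: markers are assigned, in library order, the
  theoretical adduct m/z of the bundled reference compounds, jittered
  uniformly within ±2 ppm. `generate_library` adds rejection-sampled decoy
  formulas whose adduct m/z lie > 20 ppm from *every* feature m/z (not
  just markers), so a 5 ppm search recovers exactly the planted matches —
  random noise-feature m/z would otherwise collide with laxer decoys at a
  few percent per run.
* **Bioactivity**: cluster 2 groups get *Enterococcus* zones ~16 mm
  (baseline ~8 mm) and MCF-7 IC₅₀ ~25 µg/mL (baseline ~80); cluster 1
  groups get the analogous HSF effect. The ground truth records these
  links, and "contrast markers" (those of clusters carrying a bioactivity
  effect) are the ones expected in the S-plot corners of the
  active-vs-rest OPLS-DA. The outlier group's private features carry no
  bioactivity effect — their claim is the ellipse, not the contrast.
* **QCs** are the feature-wise mean of all biological samples times
  log-normal noise of σ = 0.02, so they cluster centrally in PCA.

What the generator does **not** emulate: retention-time drift, correlated
(adduct/isotope) features, heteroscedastic detector noise, batch effects,
or missingness that depends on abundance. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not robustness to every artefact of real LC-MS campaigns.

## Problem sizes

The test suite and drivers run the generator at its default size
(2 × 250 features, 33 samples); recovery statistics aggregate 20 seeded
experiments, and the permutation null uses 20 label shuffles of a two-class
model. These sizes give stable statistics at interactive runtimes.

## Known limitations

* Dereplication matches exact mass only — no MS/MS fragments, isotope
  patterns or retention-time prediction — so annotations are tentative by
  design, as in any accurate-mass-only workflow.
* OPLS-DA fits a single predictive component; for multi-class input the
  predictive direction is the first NIPALS component of the one-hot Y,
  which is most meaningful for two-class (e.g. active vs inactive)
  contrasts.
* Q² uses globally scaled X inside CV (see above); absolute Q² values are
  therefore mildly optimistic, while orderings and the permutation null
  are unaffected in practice.
* The 4PL IC₅₀ fit assumes a monotone sigmoid; strongly biphasic
  dose-response data will fit poorly (a warning is emitted on
  non-monotonicity).
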