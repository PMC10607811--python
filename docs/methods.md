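# Methods

`psametab` reproduces, at desk scale, the computational arm of an untargeted
serum metabolomics marker-discovery study in psoriatic arthritis (PsA):
patients are graded by the Psoriasis Area and Severity Index (PASI) into
low (<5), moderate (5–10) and high (>10) skin-disease activity, and the
pipeline searches an LC-MS feature table for intensity features whose
cross-validated classification performance separates those grades. This
note records the models, the defaults and why, and what the synthetic
experiments do and do not establish.

## Synthetic cohort and feature-table model

The generator emulates the acquisition design the analysis assumes:

- **Cohort.** 150 study samples split 56/54/40 into low/moderate/high.
  PASI scores are drawn uniformly on [0.1, 4.8], [5.0, 9.8] and
  [10.1, 54.6] respectively — the observed per-group ranges of the emulated
  cohort; the wide high-group range reflects the clinical rule that
  everything above PASI 10 is "high". Both bin edges (5 and 10) belong to
  the moderate group, consistent with the inclusive "5–10" clinical
  convention; simulated draws never land on an edge.
- **Injection sequence.** Solvent and fiber blanks open the run; a pooled
  QC is injected before the first study sample and after every 10th study
  injection (16 QCs for 150 study samples). Study samples are
  block-randomized over the sequence and split across two plates.
- **Intensities.** Multiplicative model on a log-normal per-feature
  baseline (log-mean ln 1e6, log-sd 1): a per-group effect on planted
  "informative" features, ordered low < moderate < high and spanning
  `effect_size` from low to high (moderate at the geometric midpoint); a
  linear injection-order drift factor with per-feature coefficient drawn in
  [0.5, 1] × `drift_strength` (monotone increasing, shared by study samples
  and pooled QCs — blanks, injected at the run start, carry none); and
  log-normal noise with coefficient of variation `noise_cv`.
- **Defaults as study conditions.** `n_features=500`, `n_informative=20`,
  `effect_size=2` (a two-fold low-to-high shift — a moderate, realistic
  serum effect), `drift_strength=0.3` (up to 30% intensity change over the
  run, typical of a multi-day batch), `noise_cv=0.5` (biological plus
  technical variation of untargeted serum features). Pooled QCs are
  replicate injections of one pool, so they receive one tenth of the study
  CV (pure technical repeatability, ~5%).
- **Blanks.** 5% of features are background-only: intense in blanks,
  near-absent (1e-4 of baseline) elsewhere. Real features leak into blanks
  at 2% of baseline, so the ratio-5 filter has both clear keeps and clear
  removals.
- **Mass axis.** Every feature's m/z is exactly one library mass plus one
  randomly chosen polarity-compatible adduct offset, resampled until it
  falls inside the acquired range (75–1000 Th). Annotation is therefore an
  exact inverse of the generator, which the round-trip tests exploit.

What the generator does **not** model: chromatographic peak shapes, isotope
patterns, multiple adducts or in-source fragments of the same compound,
missing values, covariate (age/sex/treatment) structure, or inter-batch
effects. Passing tests therefore demonstrate the pipeline's logic is sound
and its statistics calibrated under these idealized conditions — not that
the published cohort's specific AUCs would be reproduced on real data.

## Preprocessing

Fixed order `blank_filter → serrf_normalize → glog_transform →
pareto_scale`; each step records itself on the table and the chain refuses
to re-enter out of order.

- **Blank-ratio filter.** Mean pooled-QC intensity over mean blank
  intensity, per blank type; a feature is removed if either ratio is below
  5. Mean (not median) aggregation; a zero blank mean or an absent blank
  type yields an infinite ratio and never removes. The filter is
  idempotent.
- **SERRF-style normalization.** Per feature, a random-forest regressor is
  fitted on the pooled-QC injections, predicting QC intensity from
  injection order plus the 10 most QC-correlated other features (each
  scaled by its own QC median). The fitted forest predicts a drift level
  for every injection; corrected intensity = raw × (QC median / predicted).
  Defaults: 500 trees, 10 correlated predictors, ≥5 QCs required.
  The forest grows unpruned trees **without bootstrap resampling**
  (diversity comes from per-split predictor subsampling), so it
  interpolates the QC points exactly. Two consequences, both intentional:
  a noise-free monotone drift is learned exactly (post-correction QC RSD
  ≈ 0), and the per-feature QC median is left unchanged — the correction
  reshapes, never relocates. The flip side is that the in-sample
  post-correction QC RSD also absorbs QC technical noise and is an
  optimistic diagnostic; the honest generalization estimate is the
  QC-fold cross-validated relative error reported alongside it
  (`NormalizationReport.cv_error`, computed on a 25-feature subsample).
- **Transform and scaling.** Generalized log
  `x → log2((x + sqrt(x² + λ²))/2)` with λ = 1 by default (configurable;
  behaves as log2(x) for x ≫ λ and stays finite at zero), then pareto
  scaling (centre, divide by √sd). Sample (n−1) standard deviations
  throughout. Constant features scale to zero with a warning.

Positive- and negative-mode tables are processed independently end to end.

## Feature ranking and panel building

- **AUC.** The Mann-Whitney rank statistic, (concordant + ½ tied)/(n₊·n₋),
  identical to trapezoidal integration of the empirical ROC; tested against
  both oracles exhaustively on small instances. AUCs below 0.5 are reported
  as-is — taking the best over five classifiers already guards against
  orientation pathologies, and flipping would bias the null upward.
- **Per-feature ranking.** Each feature alone is fitted by five
  classifiers — LDA, Gaussian Naive Bayes, linear-kernel SVM (margin
  scores), logistic regression, random forest — under a shared stratified
  10-fold split; out-of-fold decision scores are pooled into one AUC per
  (feature, classifier), and features are ranked by their best AUC.
  Constant features score 0.5. Under the null (no planted effects,
  n = 100/100) the best-AUC distribution spans roughly 0.34–0.64 with
  median ≈ 0.54 — the selection-maximum bias the top-k protocol inherits.
- **Panels.** For each classifier and k ∈ {1, 2, 5, 10, 20, 40, 80}, the
  top-k features are trained and evaluated by the same pooled 10-fold
  protocol; a panel passes the gate when CV-AUC ≥ 0.7. Ranking happens
  once on the full two-group dataset before panel CV, replicating the
  emulated procedure; this leaks selection information into the panel
  estimate, so a `nested=True` option re-ranks inside each training fold
  (using the vectorized rank-sum AUC of raw feature values, orientation
  free) for leakage-free estimates. The null-calibration test bounds the
  damage of the default protocol: under no planted effects fewer than 20%
  of (classifier, k) panels pass the gate.
- **Classifier roster.** Ranking uses the five above. Panel building can
  additionally use L1/L2 logistic regression, AdaBoost, gradient boosting
  (stagewise additive logistic boosting, the LogitBoost family) and an
  unpruned CART tree. Hyperparameters are fixed in the registry: SVM
  linear kernel with a 200k iteration cap (guards against libsvm stalling
  on unscaled input), plain logistic regression effectively unregularized
  (C = 1e6) to distinguish it from the explicit L2 variant (C = 1),
  boosting 100 rounds. The random forest defaults to 200 trees; fitting
  one forest per (feature, classifier, fold) makes tree count the
  dominant cost, and the heavy simulation tests and the acceptance script
  run with 10-tree forests — at a single predictor the forest's ranking
  behaviour saturates quickly and the battery's best-AUC is driven by the
  linear members.

## Annotation

Singly charged adducts only: [M+H]⁺ 1.007276, [M+Na]⁺ 22.989218,
[M+NH₄]⁺ 18.033823, [M−H]⁻ −1.007276, [M+Cl]⁻ 34.969402 Da (offsets carry
the electron adjustment — proton, not hydrogen-atom, mass — which is what
makes printed reference masses invert at sub-ppm error). For each feature
every polarity-compatible adduct is tried; the (adduct, library hit) pair
with the smallest |ppm error| is reported with `n_other_hits` counting the
remaining matches for that adduct; ties break alphabetically. Default
tolerance 5 ppm, matching Orbitrap accuracy at resolution 70,000; the
bundled golden table of 39 published marker rows inverts within 5 ppm plus
the quantization of the printed decimals (three rows sit at 5.0–5.1 ppm —
printed masses mix database and measured values). A ~40-compound reference
library bundled from those tables stands in for an online compound
database (HMDB-scale resources are out of scope). MS² spectral matching is
not modelled.

## Reporting

Per-comparison marker sets (the union of feature sets of gate-passing
panels, configurable) are intersected pairwise and triple-wise;
inclusion-exclusion consistency is property-tested against brute force.
PCA uses SVD of the column-centred matrix with a fixed sign convention
(largest-magnitude loading positive) for bit-reproducible scores; on
drift-corrected synthetic data the pooled QCs form a cluster tighter than
the study-sample spread, the standard instrumental-stability check.
`run_pipeline` wires all stages per polarity from a JSON config, logs
counts and seeds per stage, keeps partial outputs on failure (errors carry
the stage name), and writes a `summary.json` that is byte-identical across
re-runs of the same configuration.

## Problem sizes and numerical choices

- Heavy experiments are scaled for a single CPU: the drift-correction
  checks run the full 170-injection layout with 500 features at 100 trees;
  marker-recovery runs 5 seeded cohorts at 100 features (20 planted,
  effect 2); the null calibration runs 20 seeds at 80 features,
  n = 100/100, 10-tree forests. The acceptance script uses 150 features
  and a 5-seed null. These sizes are the package's choices for a desk-scale
  reproduction; all thresholds (ratio 5, gate 0.7, k-grid, 5 ppm) are the
  emulated study's.
- Determinism: every stochastic component takes a seed
  (`numpy.random.default_rng`, scikit-learn `random_state`); per-feature
  forest seeds are drawn from a generator seeded by the stage seed.
- Degenerate inputs: empty designs, missing blank types, constant
  features, non-positive QC intensities, one-class AUCs and oversized k
  all have defined behaviour (error, infinite ratio, 0.5, named error,
  error, skip-with-warning respectively).

## Known limitations

- The non-nested default ranking protocol gives optimistically biased
  panel AUCs by construction; the package reproduces that procedure
  deliberately and offers `nested=True` as the corrected variant.
- SERRF here is a per-feature forest on QC injections; it assumes drift is
  predictable from injection order and co-drifting features, and with
  ≤ 16 QCs it cannot capture high-frequency fluctuation between QC
  brackets.
- The in-sample QC RSD after correction is optimistic (see above); compare
  `cv_error` before trusting it.
- `run_pipeline` is not resumable mid-run; under a fixed seed a full
  re-run is byte-identical and cheap, which is the supported way to
  regenerate any stage.
- Published cohort-specific numbers (model AUCs such as 0.813/0.862,
  per-feature AUC columns, overlap counts) depend on the deposited raw
  cohort data and are out of desk-scale scope; the synthetic experiments
  check the properties of the procedure, not those values.
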