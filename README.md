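# psametab

Marker discovery for untargeted serum LC-MS metabolomics of psoriatic
arthritis (PsA) cohorts graded by skin-disease activity.

Patients with PsA are binned by the Psoriasis Area and Severity Index
(PASI) into low (<5), moderate (5–10) and high (>10) activity. Given a
feature table (features × injections, with per-feature m/z, retention time
and polarity) and an injection manifest (study / pooled QC / solvent blank
/ fiber blank, injection order), `psametab` runs the full discovery chain:

1. **Blank-ratio filtering** — features with pooled-QC : blank mean
   intensity ratio < 5 are removed as background.
2. **SERRF-style drift normalization** — per feature, a random forest
   fitted on the pooled-QC injections predicts the injection-order drift
   from the order plus the most QC-correlated features; intensities are
   divided by the predicted drift and re-anchored to the QC median.
3. **Generalized log + pareto scaling** —
   `x → log2((x + √(x² + λ²))/2)`, then centre and divide by √sd.
4. **AUC ranking** — every feature alone is scored by five classifiers
   (LDA, Naive Bayes, linear SVM, logistic regression, random forest)
   under pooled 10-fold CV; the ranking statistic is the Mann-Whitney AUC,
   AUC = (concordant + ½·tied) / (n₊·n₋), and features are ranked by their
   best AUC.
5. **Top-k panels** — for k ∈ {1, 2, 5, 10, 20, 40, 80} and each
   classifier, the top-k features are evaluated by 10-fold CV; panels with
   CV-AUC ≥ 0.7 are candidate marker sets.
6. **Tentative identification** — each feature's m/z is inverted through
   singly charged adduct hypotheses ([M+H]⁺, [M+Na]⁺, [M+NH₄]⁺, [M−H]⁻,
   [M+Cl]⁻) to a neutral monoisotopic mass and matched against a compound
   library within 5 ppm, reporting the best hit and the "N other hits"
   ambiguity count.
7. **Overlap reporting** — marker sets from the three severity
   comparisons (low vs high, moderate vs high, low vs moderate) are
   intersected to find features robust across contrasts.

A synthetic-data module generates the whole study design — 150-patient
cohort (56/54/40), pooled QC bracketing every 10 injections, blanks,
injection-order drift, log-normal intensities with planted group effects,
and m/z values built from known library masses — so every stage is
testable with exact ground truth and no external download.

## Worked example

```sh
python examples/03_rank_and_model.py
```

```
best single-feature AUC: 0.919 (F0001)
planted markers in the top 10 ranks: 10/10
35/35 (classifier, k) panels passed the 0.7 gate
  LDA          k=10  CV-AUC=1.000 (100% of panel is planted truth)
  NaiveBayes   k=10  CV-AUC=1.000 (100% of panel is planted truth)
  LDA          k=20  CV-AUC=1.000 (100% of panel is planted truth)
```

A synthetic cohort with 20 planted markers (two-fold low-to-high shift,
50% noise CV) is conditioned, ranked and modelled: the best single feature
separates low from high activity at AUC 0.92, all ten top-ranked features
are planted truth, and the top panels reach CV-AUC ≈ 1 because ten
moderately informative features combine. Other scripts under `examples/`
cover simulation (`01`), preprocessing with QC-RSD diagnostics (`02`),
adduct annotation of published marker rows (`04`) and the end-to-end
pipeline with overlap reporting (`05`).

The same stages are available from the shell:

```sh
psametab simulate --n-features 200 --seed 1 --out-dir run/
psametab preprocess --table run/features.csv --manifest run/manifest.csv --out run/pre/
psametab rank --table run/pre/scaled.csv --manifest run/manifest.csv --pair low_vs_high --out ranking.csv
psametab run --config config.json --out-dir run/
```

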