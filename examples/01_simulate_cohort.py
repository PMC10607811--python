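"""Generate a synthetic PASI-graded serum cohort and LC-MS feature table.

Builds the emulated acquisition: 150 patients split 56/54/40 into
low/moderate/high skin-disease activity by PASI, solvent and fiber blanks,
a pooled QC bracketing every 10 study injections, and a 500-feature
intensity matrix with planted group effects and injection-order drift.
"""

import psametab as pm

manifest = pm.generate_manifest(n_low=56, n_mod=54, n_high=40, qc_every=10, seed=1)
library = pm.generate_compound_library(300, seed=2)
table, truth = pm.generate_feature_table(
    manifest, library,
    n_features=500, n_informative=20, effect_size=2.0,
    drift_strength=0.3, noise_cv=0.5, seed=3,
)

counts = manifest.sample_type.value_counts()
print(f"injections: {len(manifest)} "
      f"(study {counts['study']}, pooled QC {counts['pooled_qc']}, "
      f"blanks {counts['solvent_blank'] + counts['fiber_blank']})")
print(f"feature table: {table.n_features} features x {table.n_samples} injections")
print(f"planted markers: {len(truth.informative_features)} "
      f"(e.g. high/low intensity ratio = {truth.effect[next(iter(truth.informative_features))]['high']:.1f})")
print(f"background (blank-only) features: {len(truth.blank_only_features)}")
# The planted markers are what the ranking stage must rediscover; the
# blank-only features are what the blank-ratio filter must remove.
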