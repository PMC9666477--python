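"""Generate a synthetic multi-lesion radiomic cohort.

Thirty patients, one third per heterogeneity archetype (homogeneous,
clustered, scattered lesion clouds), with a 40-feature six-view table
shaped like a LifeX export.  Archetypes differ only in within-patient
geometry, so per-patient mean profiles carry no archetype signal.
"""

import treehet as th

cohort = th.simulate_radiomic_table(n_patients=30, seed=0)

print(f"lesions x features: {cohort.table.n_lesions} x {cohort.table.p}")
print(f"views: {cohort.schema.views}")
print("archetype counts:")
print(cohort.truth.value_counts().to_string())
counts = cohort.table.patient_id.value_counts()
print(f"lesions per patient: min {counts.min()}, median {counts.median():.0f}, "
      f"max {counts.max()}")
# The lesion counts follow a truncated Poisson(6) on [1, 20]: most patients
# carry a handful of lesions, a few carry many -- the regime in which
# per-patient dendrograms are informative but small enough to compare exactly.
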