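"""Full stratification: distance matrix, ward clustering, baselines.

Thirty synthetic patients (ten per archetype) go through the complete
pipeline; the tree representation recovers the archetypes while the
mean-profile baseline -- blind to within-patient spread -- cannot.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import treehet as th
from treehet.pruned import DEFAULT_MU

seed = 0
cohort = th.simulate_radiomic_table(30, seed=seed)
table = th.z_normalize(th.impute_missing(cohort.table))
reduced = th.view_aware_pca(table, cohort.schema)

trees = []
for pid in reduced.patients:
    cloud = th.patient_point_cloud(reduced, pid)
    trees.append(th.average_linkage_dendrogram(
        th.lesion_distance_matrix(cloud), labels=cloud.lesion_ids))
scaled = th.rescale_heights(trees, "global")

D = th.cohort_distance_matrix(scaled, DEFAULT_MU, patient_ids=reduced.patients,
                              rng_seed=seed)
result = th.ward_cluster(D, k_range=(2, 5))
truth = cohort.truth.loc[reduced.patients].to_numpy()

print(f"selected k = {result.k}, silhouette = {result.silhouette:.3f}")
print(result.trace.to_string(index=False))
print(f"ARI vs archetype truth: {adjusted_rand_score(truth, result.labels):.3f}")

# DBSCAN on the same matrix: patients in low-density regions are noise
labels_db, report = th.dbscan_noise_check(D, eps=np.median(D.to_numpy()) / 2,
                                          min_samples=3, ward_labels=result.labels)
print(f"DBSCAN: {report['n_clusters']} clusters, {report['n_noise']} noise patients")

# baselines: biggest lesion and mean profile, same Euclidean+ward protocol
volumes = cohort.table.volume_ml.reset_index(drop=True)
for name, base in (("biggest lesion", th.baseline_biggest_lesion(reduced, volumes)),
                   ("mean vector", th.baseline_mean_vector(reduced))):
    print(f"baseline {name:14s}: k={base.k}  "
          f"ARI vs truth = {adjusted_rand_score(truth, base.labels):.3f}  "
          f"Rand vs tree labels = {th.compare_partitions(result.labels, base.labels):.3f}")
# The archetypes share their mean profile by construction, so the mean
# baseline's ARI hovers near 0 while the tree pipeline scores ~0.9: the
# dendrogram metric captures the spread structure the averages erase.

# characterize the clusters against simulated clinical covariates
clinical = th.simulate_clinical(cohort.truth, seed=seed)
report = th.characterize_clusters(
    result.labels, clinical.drop(columns=["therapy_response", "time_to_response"]),
    alpha=0.1)
sig = report[report["significant"]]
print(f"\nclinical battery: {len(report)} tests, {len(sig)} significant at alpha=0.1")
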