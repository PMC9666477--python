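# treehet

Tree-based representation and stratification of intra-tumor heterogeneity
from multi-lesion radiomic profiles.

## The problem

Patients with metastatic cancer carry several lesions at once, and how
*different* those lesions look on imaging — the intra-patient heterogeneity
of the disease — carries prognostic information that single-lesion
radiomics discards. `treehet` represents each patient as the
**average-linkage dendrogram** of their lesions' radiomic vectors and
stratifies a cohort by a metric between those dendrograms that is built to
respond to heterogeneity structure rather than to raw lesion counts or
mean profiles. It is written for imaging scientists who have a lesion-level
radiomic feature table (e.g. a LifeX export) and want an unsupervised,
acquisition-agnostic patient stratification.

## The method

1. **View-aware PCA.** Radiomic features divide into six semantic views
   (first-order statistics, shape, GLCM, GLRLM, GLZLM, NGLDM). After
   imputation and Z-normalization, a PCA is fitted per view and the top
   two components kept, giving each lesion a 12-dimensional vector with
   balanced importance across views.
2. **Patient trees.** A patient's lesions form a point cloud in R^12;
   average-linkage hierarchical clustering of the pairwise Euclidean
   distances yields a merge tree *T* — leaves are lesions, merge heights
   encode how dissimilar their phenotypes are.
3. **Edit distance.** Two rooted, unordered, edge-weighted trees are
   compared by the minimal total cost of edits — *shrink* an edge
   (cost |w − w′|), *delete/insert* an edge (cost w), *ghost/split* an
   order-2 vertex (cost 0):

       d_E(T, T′) = inf over edit paths γ from T to T′ of cost(γ)

   realized as a minimum over ancestry-preserving vertex mappings with
   ghost-aggregated chains, and computed by three mutually agreeing
   routes (exhaustive oracle, exact dynamic program, 0/1 integer program).
4. **Pruning and the measure-weighted distance.** The operator P_ε
   recursively removes leaves whose edge weighs ≤ ε (keeping the heaviest
   when all siblings qualify), collapsing near-identical phenotypes.
   Because the right ε is unknown, the patient-to-patient distance is the
   expectation over a threshold measure μ:

       d_P^μ(T, T′) = E_{ε∼μ} [ d_E(P_ε(T), P_ε(T′)) ]

   with μ = Beta(2.5, 15) by default on [0, 1]-rescaled trees (mean
   ≈ 0.143, at the saddle of the pooled merge-height density), integrated
   exactly over the breakpoint intervals of ε ↦ P_ε(T).
5. **Stratification.** Ward-linkage hierarchical clustering of the d_P^μ
   matrix with k selected in [2, 5] (silhouette with an interpretability
   band, mutual information with therapy response as tie-break), a DBSCAN
   noise check, two literature baselines (biggest lesion, mean profile),
   a Shapiro-gated clinical test battery at α = 0.1, group height-count
   curves with a permutation test, and Kaplan–Meier / log-rank summaries.

A synthetic-cohort module generates feature tables with the multi-view
correlation structure and three heterogeneity archetypes (homogeneous,
clustered, scattered) so the whole pipeline is testable end to end
without any restricted clinical data.

## Worked example

```python
import numpy as np
import treehet as th

cloud = th.PointCloud("demo", np.array([[0.0], [1.0], [10.0]]))
tree = th.average_linkage_dendrogram(th.lesion_distance_matrix(cloud),
                                     labels=["a", "b", "c"])
print(th.to_newick(tree))          # (c:9.5,(a:1,b:1):8.5);
pruned = th.prune(tree, 1.0)       # collapses the homogeneous pair {a, b}
print(th.to_newick(pruned))        # (b:9.5,c:9.5);
print(th.edit_distance(tree, pruned))   # 1.0
```

The two close lesions merge at height 1 and the outlier joins at 9.5 (the
average of 10 and 9). Pruning at ε = 1 keeps one of the two equivalent
phenotypes, whose branch absorbs the ghosted father's edge. The edit
distance between the full and the pruned tree is exactly the weight of
the deleted redundant leaf — 1.0, which also meets the total-weight lower
bound |20 − 19|, so no cheaper edit path exists.

End-to-end on a synthetic cohort (`python examples/05_stratify.py`):

```
selected k = 3, silhouette = 0.682
ARI vs archetype truth: 0.898
baseline mean vector   : k=2  ARI vs truth = 0.083
```

Ward clustering on the pruned edit distances recovers the three planted
heterogeneity archetypes almost perfectly, while the mean-profile
baseline — blind to within-patient spread by construction of the
cohort — stays near chance. The `examples/` directory has one short
script per capability; the `treehet` command-line tool exposes the same
stages as `simulate`, `reduce`, `trees`, `dist`, `cluster`,
`characterize`, `baselines` and `run` subcommands.

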