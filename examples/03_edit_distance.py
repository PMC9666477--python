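"""The merge-tree edit distance and the pruning operator.

Edits: shrink an edge (cost = weight change), delete/insert an edge
(cost = its weight), ghost/split an order-2 vertex (free).  The distance
is the cheapest edit path, computed three ways that must agree: an
exhaustive mapping oracle, an exact dynamic program, and an integer
program.
"""

import numpy as np

import treehet as th

# 1-d lesions at {0, 1, 10}: the two close lesions merge at height 1,
# the outlier joins at 9.5 (average linkage)
cloud = th.PointCloud("demo", np.array([[0.0], [1.0], [10.0]]))
tree = th.average_linkage_dendrogram(th.lesion_distance_matrix(cloud),
                                     labels=["a", "b", "c"])
print("tree:", th.to_newick(tree), " total weight:", th.total_weight(tree))

# pruning at eps=1 collapses the homogeneous pair {a, b} into one
# phenotype whose branch absorbs the ghosted father's edge
pruned = th.prune(tree, 1.0, rng_seed=0)
print("P_1(tree):", th.to_newick(pruned))

for solver in ("oracle", "dp", "milp"):
    print(f"d_E(tree, pruned) via {solver}: "
          f"{th.edit_distance(tree, pruned, solver=solver):.6f}")
# All three give 1.0: delete the redundant leaf (weight 1), ghost its
# father for free.  This also meets the lower bound |20 - 19| from the
# total weights, so no cheaper edit path can exist.

leaf3 = th.from_newick("(a:3);")
leaf5 = th.from_newick("(a:5);")
print("d_E(leaf 3, leaf 5):", th.edit_distance(leaf3, leaf5))
# 2.0: shrinking the single branch from weight 3 to 5 costs |3-5| and
# beats deleting and re-inserting (cost 8).
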