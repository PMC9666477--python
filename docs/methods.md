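# Methods

This note records the model, the conventions and the numerical choices
behind `treehet`, in the order the pipeline runs them.

## Preprocessing and view-aware reduction

Radiomic exports are high-dimensional and strongly collinear, with the
collinearity concentrated *within* the six semantic views (first-order,
shape, GLCM, GLRLM, GLZLM, NGLDM): indices of one view are different
functionals of the same texture matrix. Reduction is therefore per view:
after per-feature median imputation (configurable to mean) and
Z-normalization with denominator n − 1, each view's sub-matrix gets its
own PCA and contributes its two leading components, so every lesion
becomes a 12-vector in which no view dominates by feature count.

Conventions: normalization statistics and the PCAs are fitted on the
pooled lesions of the whole cohort (patients must share one reduced
space); constant feature columns are dropped with a warning rather than
an error, since real exports contain them; the sign of each component is
fixed by making its largest-magnitude loading positive, which makes the
whole reduction bit-reproducible.

## Merge trees

A patient's lesions form a point cloud; unweighted average-linkage
(UPGMA-update) agglomeration of the pairwise Euclidean distances gives a
dendrogram, read as a merge tree: leaves at height 0, internal vertices
at the agglomeration heights, the root at the final merge, and the edge
weight of a vertex equal to the height gap to its father. Average
linkage is fixed for the within-patient step because it is the least
outlier-sensitive of the standard updates. A single-lesion patient is a
single-vertex tree of height 0 — it carries no heterogeneity information,
and downstream it behaves like an extreme homogeneous patient.

Cohort trees are rescaled before distance computation. The default
divides every height by the cohort-wide maximum root height ("global"),
preserving between-patient scale ratios; "per_tree" rescaling (every
root to 1) is available for analyses that only care about shape. The
default threshold measure assumes the global mode.

## Edit distance between merge trees

Edits and costs: shrinking an edge from weight w to w′ costs |w − w′|;
deleting or inserting an edge costs its weight; ghosting an order-2
vertex (merging its two edges by summing weights) and its inverse,
splitting, are free — so order-2 vertices are irrelevant and trees are
compared modulo ghosting.

The infimum over edit paths is realized by combinatorial *mappings*: a
one-to-one pairing of vertices containing the two roots that preserves
the ancestor relation in both directions. Vertices outside the *kept
subtree* (the union of paths from matched vertices to the root) are
deleted or inserted at the cost of their edge; unmatched vertices inside
the kept subtree must have exactly one kept child — they are ghosted for
free, and their weights aggregate onto the chain of the nearest matched
descendant; each matched pair pays the shrink cost between its
aggregated chain weights h(nma(a)) − h(a), where nma is the nearest
matched ancestor. The requirement that every branching vertex of the
kept subtree be matched is what makes the ghost-reduced kept subtrees
isomorphic and the cost decomposition unambiguous.

Three routes compute the same value:

* an **exhaustive oracle** enumerating every chain-valid matched set on
  both sides and every skeleton isomorphism between them (definitional
  semantics; bounded at 9 vertices per tree);
* the default **dynamic program**: the mapping class decomposes exactly
  by child subtrees — for each matched pair, child subtrees are assigned
  to each other (or deleted/inserted) by a linear-sum assignment whose
  pair costs minimize over the kept descendant in each subtree — giving
  an exact polynomial algorithm;
* a **0/1 integer program** over variables "vertex a is matched with
  nearest matched ancestor α to vertex b with ancestor β", with one
  constraint per vertex (at most one chain may pass through or out of
  it) and chain-consistency constraints, solved by HiGHS.

The suite holds the solvers to the oracle at 1e-9 and checks the metric
axioms, the total-weight bounds |ΣW − ΣW′| ≤ d_E ≤ ΣW + ΣW′, and
1-Lipschitz behaviour in any single edge weight. Canonical forms
(sibling-sorted encodings after ghosting, weights rounded at 1e-12) give
the equality test: d_E = 0 exactly on equal canonical forms.

## Pruning

P_ε marks every leaf whose father-child edge weighs ≤ ε (the comparison
is exactly ≤, so ε-intervals of constancy are right-open). If at least
one sibling survives, all marked leaves are deleted; if *all* children
of a father are marked leaves, the heaviest is kept — a seeded uniform
choice among ties, which only affects leaf labels since tied leaves are
isomorphic. Fathers left with a single child are ghosted (never the
root, which has no father), so the kept leaf's edge absorbs the chain
above it, and the rule iterates to a fixpoint. The result always retains
at least one leaf, P_ε is idempotent, and leaf counts are non-increasing
in ε.

Because ghost-aggregated chains always start at an original leaf and
grow upward contiguously, every threshold at which P_ε(T) can change is
a prefix sum of weights along some leaf-to-root path. The breakpoint
profile evaluates the pruning at each candidate (left-closed) and merges
consecutive intervals with equal canonical forms, so it is exact — the
suite verifies it against direct pruning at random thresholds.

## The measure-weighted pruned distance

d_P^μ(T, T′) = E_{ε∼μ}[d_E(P_ε(T), P_ε(T′))]. Any finite positive
measure is accepted and normalized to a probability measure first, so
the integral is the stated expectation. The default is Beta(2.5, 15):
pooled rescaled merge heights of a multi-lesion cohort are typically
bimodal — a low mode of within-phenotype merges and a high mode of
between-phenotype merges — and the Beta mean 2.5/17.5 ≈ 0.143 sits at
the saddle (≈ 0.15) between them, down-weighting both uninformative
extremes of ε. `fit_mu` re-centers the measure for a new cohort: a
Gaussian KDE of the pooled internal heights locates the local minimum
between the two largest modes and the Beta mean is pinned there with
α = 2.5 fixed via β = α(1 − s)/s; with no interior saddle it falls back
to the default with a warning.

Integration is exact: the merged breakpoints of both profiles cut ε into
finitely many right-open intervals on which both pruned trees are
constant; each interval contributes d_E(segment pair) × μ(interval),
with interval masses from the Beta CDF or atom sums. A grid-quadrature
mode (Voronoi-cell masses around explicit grid points, pruning at each
point) provides an independent route; the two agree within relative
1e-3 on random pairs, and a point mass at 0 recovers plain d_E. Equal-
mass quantile discretizations of the Beta converge to the exact value
(weak convergence robustness), within 1% at 100 atoms.

Cohort matrices compute pruning profiles once per tree and memoize edit
distances by canonical-form pairs; entries are independent pairwise
calls, so the result does not depend on evaluation order. Tie-break
seeds derive deterministically from one master seed.

## Stratification

Ward-linkage agglomeration on the condensed d_P^μ matrix, cutting at
each k in [2, 5]. Selection trades similarity performance against
interpretability: all candidates whose silhouette (precomputed metric)
lies within 0.05 of the range maximum count as "reasonable"; among them,
the mutual information with therapy response decides when a response
column is supplied, otherwise the smallest such k is taken. The full
trace (silhouette and concordance per k) is always returned. A DBSCAN
pass on the same matrix flags low-density patients as noise and reports
Rand agreement with the ward labels on the non-noise core.

Baselines follow the single-lesion radiomics literature: (i) each
patient represented by the reduced vector of their largest-volume lesion
(ties broken by lowest lesion id), (ii) by the mean of their lesions'
reduced vectors — both clustered with the same Euclidean + ward
protocol. Partition agreement uses the plain Rand index by pair
counting.

The clinical battery runs per group pair: numeric variables pass a
Shapiro gate (level 0.05, per group, n ≥ 3, otherwise non-parametric
with a warning) into a t-test (normal) or Mann–Whitney for location and
Bartlett (normal) or Brown–Forsythe Levene for variance; categorical
variables get a plain chi-squared independence test — the Yates
correction is deliberately off, as it is markedly conservative on 2×2
tables at these group sizes. Significance is flagged on the two-sided
p-value at α = 0.1; the one-sided p-value oriented by the observed
difference is reported alongside but not used for flagging, because a
data-oriented one-sided flag would double the null false-positive rate.
Raw p-values are reported; Benjamini–Hochberg adjustment is available
behind a flag. Identical constant samples short-circuit to a defined
degenerate output (p = 1).

Group height-count curves report, per threshold, the number of internal
vertices above it (leaves sit at height 0 and would only add a
constant), with group means and one-SD bands. Group differences are
scored by a pointwise one-way F statistic under label permutation, both
raw and with a max-statistic (Westfall–Young style) adjustment over the
grid — a deliberately simple, documented substitute for interval-wise
functional testing. Survival summaries are product-limit curves per
group with the multivariate log-rank test (lifelines).

## Synthetic cohorts

The generator emulates the structure the method assumes, not any real
dataset. Three archetypes, differing in within-patient geometry only:

* homogeneous — one Gaussian cloud with typical inter-lesion distance
  σ_within = 0.2;
* clustered — two sub-clusters of spread σ_within whose centers sit at
  distance Δ = 3.0 (the number of sub-clusters is configurable, ≥ 2);
* scattered — one broad cloud with typical inter-lesion distance Δ/2:
  lesions vary continuously without forming distinct phenotypes, so the
  spread is large but below the between-phenotype separation.

σ_within and Δ are characteristic *distances*: per-coordinate Gaussian
scales divide by √(2·dim) so that the stated values are the typical
pairwise distances regardless of the latent dimension (4 by default).
This keeps the three height scales in the regime the measure expects —
homogeneous merges below the Beta saddle, clustered bridges at the top
of the scale, scattered merges in between — and the pooled height
density bimodal with an interior valley. Patient centers are drawn
independently of the archetype (SD 1.0), so mean lesion profiles carry
no archetype signal and the mean-vector baseline is blind by
construction. Lesion counts follow a truncated Poisson(6) on [1, 20].

Feature tables mimic multi-view collinearity: each view reads the latent
position through its own random 2-plane and spreads the two view scores
densely over its features (features of a view are near-duplicates,
giving strong within-view correlation; views overlap only through their
planes), plus a per-patient view factor (SD 0.1, an acquisition-style
shift moving all of a patient's lesions coherently) and i.i.d.
measurement noise (SD 0.05, small relative to the biological signal).
Per-view PCA with two components recovers each view's plane, which is
the regime the reduction step is designed for.

What passing tests show — and don't: the generator plants exactly the
geometry the representation measures, with modest noise and no scanner
batch effects, segmentation variability, non-linear feature couplings or
archetype-correlated lesion counts. Recovery results on it demonstrate
the machinery's correctness and its contrast with mean-profile
baselines, not expected performance on clinical data. Single-lesion
patients (≈ 1.5% under the count law) are a known failure mode: their
bare trees gravitate to the homogeneous cluster whatever their true
archetype.

Clinical covariates are drawn per patient with declared group effects
(location shifts, response hazard scales); zero effects give an
exchangeable null table used for calibration studies. Times to response
are exponential with censoring at a fixed horizon.

## Problem sizes and runtime choices

The exhaustive oracle enumerates up to 9 vertices per tree; solver
agreement is checked on 100 random pairs with ≤ 5 edges each. Metric
suites run on trees with ≤ 6 leaves (200 pairs, 60 triples). Exact
versus grid integration uses 50 random pairs against a 10^4-point grid.
End-to-end recovery uses 30 patients (10 per archetype) across 5 master
seeds — large enough for stable silhouettes and small enough that a full
5-seed run takes well under a minute. The battery calibration uses 100
replicates of two 30-patient groups, alternating normal and lognormal
markers to exercise both sides of the Shapiro gate.

## Known limitations

* The edit-distance dynamic program is exact for the mapping semantics
  defined here; trees with hundreds of leaves would need the memoized
  cohort path and patience, though patient trees (≤ 20 lesions) are far
  below that.
* d_P^μ still grows with the number of surviving phenotypes, so cohorts
  whose heterogeneous patients differ wildly in lesion count will show
  diffuse heterogeneous clusters — pruning mitigates the cardinality
  effect for homogeneous structure only.
* The permutation height-curve test is pointwise with a max-statistic
  adjustment, not an interval-wise procedure; it controls the family-wise
  error over the grid but does not localize significant intervals with
  interval-wise guarantees.
* `fit_mu`'s saddle detection assumes a (near-)bimodal pooled height
  density; cohorts dominated by mid-scale heterogeneity can push the
  fitted mean far from the default, which is worth inspecting before
  use.
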