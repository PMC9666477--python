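"""Cohort stratification and cluster characterization.

Patients are clustered from the pruned-edit-distance matrix by
agglomerative clustering with ward linkage, the number of clusters chosen
over [2, 5] by silhouette (ties broken by mutual information with therapy
response when available).  A DBSCAN pass on the same matrix flags
low-density patients as noise.  Two literature baselines are provided for
comparison: clustering patients by their single biggest lesion, and by the
mean of their lesions' reduced vectors.  Cluster characterization follows
a Shapiro-gated battery (t/Mann-Whitney for location, Bartlett/Levene for
variance, chi-squared for categorical independence) at alpha = 0.1, plus
group height-count curves with a permutation test and Kaplan-Meier /
log-rank survival summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import DBSCAN
from sklearn.metrics import mutual_info_score, rand_score, silhouette_score

from .errors import CapacityError, DataError
from .mergetree import MergeTree, height_count_curve

__all__ = [
    "ClusteringResult",
    "ward_cluster",
    "dbscan_noise_check",
    "baseline_biggest_lesion",
    "baseline_mean_vector",
    "compare_partitions",
    "characterize_clusters",
    "group_height_curves",
    "km_logrank",
]

SHAPIRO_GATE = 0.05


@dataclass
class ClusteringResult:
    """Labels plus the full model-selection trace."""

    labels: np.ndarray
    k: int
    silhouette: float
    linkage: str
    trace: pd.DataFrame
    patient_ids: list | None = None

    def as_series(self) -> pd.Series:
        idx = self.patient_ids if self.patient_ids is not None else range(len(self.labels))
        return pd.Series(self.labels, index=idx, name="cluster")


def _as_matrix(D) -> tuple[np.ndarray, list | None]:
    if isinstance(D, pd.DataFrame):
        return D.to_numpy(dtype=float), list(D.index)
    return np.asarray(D, dtype=float), None


def ward_cluster(
    D,
    k_range=(2, 5),
    response=None,
    linkage_name: str = "ward",
    silhouette_tolerance: float = 0.05,
) -> ClusteringResult:
    """Hierarchical clustering of the patient distance matrix.

    ``k`` is selected over ``k_range`` as a trade-off between similarity
    performance and interpretability: among the candidates whose
    silhouette lies within ``silhouette_tolerance`` of the range maximum
    (silhouette is on a fixed [-1, 1] scale, so the band is absolute),
    the concordance (mutual information) with ``response``
    decides when a response is supplied, otherwise the smallest such k is
    taken.  The selection trace (silhouette and concordance per candidate
    k) is always returned.
    """
    M, ids = _as_matrix(D)
    n = M.shape[0]
    kmin, kmax = int(k_range[0]), int(k_range[-1])
    if n < max(3, kmin):
        raise CapacityError(f"need at least {max(3, kmin)} patients, got {n}")
    Z = linkage(squareform(M, checks=False), method=linkage_name)
    rows = []
    candidates = {}
    for k in range(kmin, min(kmax, n) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
        k_eff = len(np.unique(labels))
        sil = (
            float(silhouette_score(M, labels, metric="precomputed"))
            if 2 <= k_eff < n
            else float("nan")
        )
        mi = (
            float(mutual_info_score(np.asarray(response), labels))
            if response is not None
            else float("nan")
        )
        rows.append({"k": k, "k_effective": k_eff, "silhouette": sil, "mutual_information": mi})
        candidates[k] = (labels, sil, mi)
    trace = pd.DataFrame(rows)
    valid = [k for k in candidates if np.isfinite(candidates[k][1])]
    if not valid:
        warnings.warn("degenerate distance matrix: returning k = minimum of the range",
                      stacklevel=2)
        k_best = kmin
        labels = candidates[kmin][0]
        sil = float("nan")
    else:
        best_sil = max(candidates[k][1] for k in valid)
        cutoff = best_sil - silhouette_tolerance
        near = sorted(k for k in valid if candidates[k][1] >= cutoff - 1e-12)
        if response is not None and len(near) > 1:
            k_best = max(near, key=lambda k: (candidates[k][2], -k))
        else:
            k_best = near[0]
        labels, sil, _ = candidates[k_best]
    return ClusteringResult(labels, int(k_best), sil, linkage_name, trace, ids)


def dbscan_noise_check(D, eps: float, min_samples: int = 3, ward_labels=None):
    """Density clustering on the precomputed matrix; noise labelled -1.

    Returns ``(labels, report)`` where the report holds the noise count
    and, when ward labels are supplied, the Rand agreement restricted to
    non-noise patients.
    """
    M, ids = _as_matrix(D)
    if eps <= 0:
        raise ValueError("eps must be positive")
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit_predict(M)
    report = {"n_noise": int((labels == -1).sum()), "n_clusters": int(len(set(labels) - {-1}))}
    if ward_labels is not None:
        core = labels != -1
        report["rand_with_ward_core"] = (
            float(rand_score(np.asarray(ward_labels)[core], labels[core]))
            if core.sum() >= 2
            else float("nan")
        )
    if ids is not None:
        labels = pd.Series(labels, index=ids, name="dbscan")
    return labels, report


def _cluster_vectors(vectors: pd.DataFrame, k_range, response):
    X = vectors.to_numpy(dtype=float)
    diff = X[:, None, :] - X[None, :, :]
    D = pd.DataFrame(np.sqrt((diff**2).sum(axis=2)),
                     index=vectors.index, columns=vectors.index)
    return ward_cluster(D, k_range=k_range, response=response)


def baseline_biggest_lesion(reduced, volumes=None, k_range=(2, 5), response=None) -> ClusteringResult:
    """Single-lesion baseline: each patient = its largest-volume lesion.

    Reduced vectors of the volume-maximal lesion per patient (ties broken
    by lowest lesion id) are clustered with the same Euclidean + ward
    protocol as the tree pipeline.
    """
    frame = reduced.to_frame()
    if volumes is None:
        raise DataError("baseline_biggest_lesion requires lesion volumes")
    vols = pd.to_numeric(pd.Series(np.asarray(volumes)), errors="coerce")
    if vols.isna().any():
        raise DataError("missing lesion volumes: cannot select the biggest lesion")
    frame = frame.assign(_volume=vols.values)
    frame = frame.sort_values(["patient_id", "_volume", "lesion_id"],
                              ascending=[True, False, True], kind="mergesort")
    top = frame.groupby("patient_id", sort=True).first()
    vectors = top[reduced.columns]
    return _cluster_vectors(vectors, k_range, response)


def baseline_mean_vector(reduced, k_range=(2, 5), response=None) -> ClusteringResult:
    """Mean-profile baseline: each patient = average of its lesion vectors."""
    frame = reduced.to_frame()
    vectors = frame.groupby("patient_id", sort=True)[reduced.columns].mean()
    return _cluster_vectors(vectors, k_range, response)


def compare_partitions(a, b) -> float:
    """Rand index between two partitions of the same patients."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"partition lengths differ: {a.shape} vs {b.shape}")
    return float(rand_score(a, b))


def _pairwise_tests(x: np.ndarray, y: np.ndarray) -> list[dict]:
    """Shapiro-gated location and variance tests for one variable pair."""
    out = []
    if np.ptp(np.concatenate([x, y])) == 0:
        # identical constant samples: no test is informative
        return [
            {"family": "mean/distribution", "test": "degenerate", "statistic": np.nan,
             "p_two_sided": 1.0, "p_one_sided": 1.0},
            {"family": "variance", "test": "degenerate", "statistic": np.nan,
             "p_two_sided": 1.0, "p_one_sided": np.nan},
        ]
    small = len(x) < 3 or len(y) < 3
    if small:
        warnings.warn("group too small for the Shapiro gate; using non-parametric tests",
                      stacklevel=3)
        normal = False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = (stats.shapiro(x).pvalue > SHAPIRO_GATE
                      and stats.shapiro(y).pvalue > SHAPIRO_GATE)
    sign = np.sign(np.mean(x) - np.mean(y)) or 1.0
    if normal:
        t = stats.ttest_ind(x, y)
        one = stats.ttest_ind(x, y, alternative="greater" if sign > 0 else "less")
        out.append(("mean/distribution", "t-test", t.statistic, t.pvalue, one.pvalue))
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            b = stats.bartlett(x, y)
            out.append(("variance", "bartlett", b.statistic, b.pvalue, np.nan))
        else:
            out.append(("variance", "bartlett", np.nan, np.nan, np.nan))
    else:
        if np.ptp(np.concatenate([x, y])) == 0:
            out.append(("mean/distribution", "mann-whitney", np.nan, 1.0, 1.0))
            out.append(("variance", "levene", np.nan, 1.0, np.nan))
        else:
            u = stats.mannwhitneyu(x, y)
            one = stats.mannwhitneyu(x, y, alternative="greater" if sign > 0 else "less")
            out.append(("mean/distribution", "mann-whitney", u.statistic, u.pvalue, one.pvalue))
            lv = stats.levene(x, y)
            out.append(("variance", "levene", lv.statistic, lv.pvalue, np.nan))
    return [
        {"family": fam, "test": name, "statistic": s, "p_two_sided": p, "p_one_sided": p1}
        for fam, name, s, p, p1 in out
    ]


def characterize_clusters(
    labels,
    clinical: pd.DataFrame,
    alpha: float = 0.1,
    categorical: tuple[str, ...] | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Pairwise test battery of clinical covariates across clusters.

    Numeric variables: Shapiro-gated t-test (else Mann-Whitney) for
    location and Bartlett (else Levene) for variance, per group pair.
    Categorical variables: chi-squared independence on the pair's
    contingency table.  Significance is flagged on the two-sided p at
    ``alpha``; the one-sided p oriented by the observed difference is
    reported alongside.  ``bh_adjust`` adds Benjamini-Hochberg adjusted
    p-values (raw values are always reported).
    """
    labels = pd.Series(np.asarray(labels), index=clinical.index, name="cluster")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise DataError("need at least 2 groups to characterize")
    if categorical is None:
        categorical = tuple(
            c for c in clinical.columns
            if clinical[c].dropna().isin([0, 1]).all() or clinical[c].dtype == object
        )
    rows = []
    for col in clinical.columns:
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                xa = clinical.loc[labels == ga, col].dropna()
                xb = clinical.loc[labels == gb, col].dropna()
                base = {"variable": col, "group_a": ga, "group_b": gb}
                if col in categorical:
                    tab = pd.crosstab(
                        labels[labels.isin([ga, gb])],
                        clinical.loc[labels.isin([ga, gb]), col],
                    )
                    if tab.shape[1] < 2 or tab.shape[0] < 2:
                        rows.append(base | {"family": "independence", "test": "chi2",
                                            "statistic": np.nan, "p_two_sided": 1.0,
                                            "p_one_sided": np.nan})
                        continue
                    # plain chi-squared: the Yates correction is markedly
                    # conservative on 2x2 tables at these group sizes
                    chi = stats.chi2_contingency(tab, correction=False)
                    rows.append(base | {"family": "independence", "test": "chi2",
                                        "statistic": chi.statistic,
                                        "p_two_sided": chi.pvalue, "p_one_sided": np.nan})
                else:
                    for rec in _pairwise_tests(xa.to_numpy(float), xb.to_numpy(float)):
                        rows.append(base | rec)
    report = pd.DataFrame(rows)
    report["significant"] = report["p_two_sided"] < alpha
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        ok = report["p_two_sided"].notna()
        adj = np.full(len(report), np.nan)
        adj[ok.to_numpy()] = multipletests(report.loc[ok, "p_two_sided"], method="fdr_bh")[1]
        report["p_adjusted"] = adj
    return report


@dataclass
class GroupCurves:
    """Group height-count summaries plus permutation significance."""

    grid: np.ndarray
    means: pd.DataFrame  # groups x grid
    sds: pd.DataFrame
    f_statistic: np.ndarray
    p_pointwise: np.ndarray
    p_adjusted: np.ndarray  # max-statistic (Westfall-Young style) adjustment


def _f_per_point(curves: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> np.ndarray:
    n, g = len(labels), len(groups)
    grand = curves.mean(axis=0)
    between = np.zeros(curves.shape[1])
    within = np.zeros(curves.shape[1])
    for lab in groups:
        sel = curves[labels == lab]
        between += len(sel) * (sel.mean(axis=0) - grand) ** 2
        within += ((sel - sel.mean(axis=0)) ** 2).sum(axis=0)
    dfb, dfw = g - 1, n - g
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (between / dfb) / (within / dfw)
    F[~np.isfinite(F)] = 0.0
    return F


def group_height_curves(
    trees: list[MergeTree],
    labels,
    grid,
    n_permutations: int = 500,
    rng_seed: int = 0,
) -> GroupCurves:
    """Group-wise mean/SD height-count curves with a permutation test.

    The group difference at each threshold is scored by a one-way F
    statistic; significance is assessed by label permutation, both
    pointwise and with a max-statistic adjustment over the grid.
    """
    grid = np.asarray(grid, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise DataError("need at least 2 groups")
    curves = np.array([height_count_curve(t, grid).counts for t in trees], dtype=float)
    means = pd.DataFrame(
        {g: curves[labels == g].mean(axis=0) for g in groups}).T
    sds = pd.DataFrame(
        {g: curves[labels == g].std(axis=0, ddof=0) for g in groups}).T
    F = _f_per_point(curves, labels, groups)
    rng = np.random.default_rng(rng_seed)
    exceed = np.zeros_like(F)
    exceed_max = np.zeros_like(F)
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        Fp = _f_per_point(curves, perm, groups)
        exceed += Fp >= F
        exceed_max += Fp.max() >= F
    p_point = (exceed + 1.0) / (n_permutations + 1.0)
    p_adj = (exceed_max + 1.0) / (n_permutations + 1.0)
    return GroupCurves(grid, means, sds, F, p_point, p_adj)


def km_logrank(labels, time_to_response, event_flag):
    """Kaplan-Meier curves per group and the multivariate log-rank test.

    Empty groups are dropped with a warning.  Returns a dict with one
    survival-function DataFrame per group, the log-rank statistic and its
    p-value.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    labels = np.asarray(labels)
    time = np.asarray(time_to_response, dtype=float)
    event = np.asarray(event_flag, dtype=int)
    if (time < 0).any():
        raise DataError("times must be nonnegative")
    curves = {}
    keep = np.ones(len(labels), dtype=bool)
    for g in np.unique(labels):
        sel = labels == g
        if sel.sum() == 0:
            warnings.warn(f"dropping empty group {g!r}", stacklevel=2)
            keep &= ~sel
            continue
        km = KaplanMeierFitter()
        km.fit(time[sel], event[sel], label=str(g))
        curves[g] = km.survival_function_
    if len(curves) >= 2:
        res = multivariate_logrank_test(time[keep], labels[keep], event[keep])
        stat, p = float(res.test_statistic), float(res.p_value)
    else:
        stat, p = float("nan"), float("nan")
    return {"curves": curves, "statistic": stat, "p_value": p}
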