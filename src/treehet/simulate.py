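"""Synthetic cohorts with the statistical structure the method assumes.

Three heterogeneity archetypes mirror the qualitative tree shapes the
representation is designed to separate:

* ``homogeneous`` — a condensed point cloud: one tight Gaussian, all
  merges near zero, trees prune down to a single short branch;
* ``clustered`` — a few well-separated tight sub-clusters: low merge
  blocks joined by tall edges;
* ``scattered`` — one broad cloud: merges spread far from zero.

Crucially, archetypes differ in *within-patient geometry only*: patient
centers are drawn independently of the archetype, so a patient's mean
lesion profile carries no archetype signal while the dendrogram does.

Radiomic feature tables mimic the multi-view collinearity of LifeX-style
exports: each semantic view reads the latent lesion position through its
own two-dimensional plane and spreads the two view scores densely over
its features, so features within a view are near-duplicates while views
overlap only through their planes.  A per-patient view factor
(acquisition-style shift) and i.i.d. measurement noise complete the
model.  Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .mergetree import MergeTree, PointCloud
from .preprocess import RadiomicTable, ViewSchema, default_schema

__all__ = [
    "ArchetypeSpec",
    "SyntheticCohort",
    "DEFAULT_ARCHETYPES",
    "simulate_point_cloud",
    "simulate_radiomic_table",
    "simulate_clinical",
    "random_merge_tree",
]

# declared geometry constants (reduced-space units)
SIGMA_WITHIN = 0.2
DELTA = 3.0
LESION_RATE = 6.0  # truncated Poisson on [1, 20]
LESION_MAX = 20

ARCHETYPE_NAMES = ("homogeneous", "clustered", "scattered")


@dataclass
class ArchetypeSpec:
    """Geometry of one heterogeneity archetype."""

    name: str
    sigma_within: float = SIGMA_WITHIN
    delta: float = DELTA
    n_subclusters: int = 2
    lesion_rate: float = LESION_RATE

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPE_NAMES:
            raise ConfigurationError(f"unknown archetype {self.name!r}")
        if self.sigma_within <= 0:
            raise ConfigurationError("sigma_within must be positive")
        if self.delta < 0:
            raise ConfigurationError("delta must be nonnegative")
        if self.name == "clustered" and self.n_subclusters < 2:
            raise ConfigurationError("clustered archetype needs >= 2 sub-clusters")


DEFAULT_ARCHETYPES = {name: ArchetypeSpec(name) for name in ARCHETYPE_NAMES}


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    out = np.empty(size, dtype=np.int64)
    for i in range(size):
        while True:
            n = rng.poisson(lam)
            if 1 <= n <= LESION_MAX:
                out[i] = n
                break
    return out


def _archetype_positions(
    spec: ArchetypeSpec, n_lesions: int, dim: int, rng: np.random.Generator
) -> np.ndarray:
    """Latent lesion positions; ``sigma_within``/``delta`` are typical
    inter-lesion *distances*, so per-coordinate scales divide by sqrt(2 dim)."""
    unit = 1.0 / np.sqrt(2.0 * dim)
    if spec.name == "homogeneous":
        return rng.normal(scale=spec.sigma_within * unit, size=(n_lesions, dim))
    if spec.name == "scattered":
        # broad cloud: spread scaled by the phenotype separation, but below
        # it -- lesions vary continuously without forming distinct phenotypes
        return rng.normal(scale=spec.delta / 2.0 * unit, size=(n_lesions, dim))
    # clustered: sub-cluster centers at pairwise distance delta
    k = spec.n_subclusters
    basis = np.linalg.qr(rng.normal(size=(dim, k)))[0].T  # k orthonormal rows
    centers = (spec.delta / np.sqrt(2.0)) * basis
    assign = np.concatenate([np.arange(k), rng.integers(k, size=max(n_lesions - k, 0))])
    rng.shuffle(assign)
    assign = assign[:n_lesions]
    return centers[assign] + rng.normal(scale=spec.sigma_within * unit,
                                        size=(n_lesions, dim))


def simulate_point_cloud(
    archetype: ArchetypeSpec | str,
    n_lesions: int,
    dim: int = 12,
    seed: int | np.random.Generator = 0,
    patient_id: object = "sim",
) -> PointCloud:
    """Sample one patient's lesion cloud from an archetype geometry."""
    if isinstance(archetype, str):
        archetype = DEFAULT_ARCHETYPES[archetype] if archetype in DEFAULT_ARCHETYPES \
            else ArchetypeSpec(archetype)
    if n_lesions < 1:
        raise ConfigurationError("n_lesions must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = _archetype_positions(archetype, n_lesions, dim, rng)
    return PointCloud(patient_id, pts)


@dataclass
class SyntheticCohort:
    """A generated cohort: feature table, truth labels, optional clinical."""

    table: RadiomicTable
    truth: pd.Series  # archetype name per patient
    schema: ViewSchema
    seed: int
    clinical: pd.DataFrame | None = None
    latent: pd.DataFrame | None = field(default=None, repr=False)


def _generic_schema(p: int, views: int) -> ViewSchema:
    base, extra = divmod(p, views)
    if base < 2:
        raise ConfigurationError(
            f"cannot split p={p} features into {views} views with >= 2 features each"
        )
    mapping = {}
    i = 0
    for v in range(views):
        for _ in range(base + (1 if v < extra else 0)):
            mapping[f"view{v + 1}_f{i}"] = f"view{v + 1}"
            i += 1
    return ViewSchema(mapping)


def simulate_radiomic_table(
    n_patients: int,
    archetype_mix: dict[str, float] | None = None,
    p: int = 40,
    views: int = 6,
    missing_rate: float = 0.0,
    seed: int = 0,
    latent_dim: int = 4,
    noise_sd: float = 0.05,
    factor_sd: float = 0.1,
    center_sd: float = 1.0,
) -> SyntheticCohort:
    """Generate a lesion-level radiomic table with multi-view structure.

    ``archetype_mix`` maps archetype name to cohort proportion (default:
    one third each).  Latent lesion positions follow the archetype
    geometry around an archetype-independent patient center; each view's
    feature block carries two view scores (the latent position read
    through the view's random plane) spread densely over its features,
    plus a per-patient view factor and i.i.d. measurement noise.
    """
    if archetype_mix is None:
        archetype_mix = {name: 1.0 / 3.0 for name in ARCHETYPE_NAMES}
    if abs(sum(archetype_mix.values()) - 1.0) > 1e-9:
        raise ConfigurationError("archetype mix proportions must sum to 1")
    schema = default_schema() if (p == 40 and views == 6) else _generic_schema(p, views)
    rng = np.random.default_rng(seed)

    # archetype assignment: largest-remainder rounding of the mix
    names = sorted(archetype_mix)
    quota = {n: archetype_mix[n] * n_patients for n in names}
    counts = {n: int(np.floor(quota[n])) for n in names}
    for n in sorted(names, key=lambda n: quota[n] - counts[n], reverse=True):
        if sum(counts.values()) < n_patients:
            counts[n] += 1
    truth = [n for n in names for _ in range(counts[n])]
    rng.shuffle(truth)

    feat_names = schema.features
    view_feats = {v: schema.features_of_view(v) for v in schema.views}
    # each view reads the latent position through its own 2-dim plane and
    # spreads the two view scores densely over its features: features of a
    # view are near-duplicates (strong within-view correlation), views
    # overlap only through their random planes (weaker between-view
    # correlation), and per-view PCA with 2 components recovers the plane
    maps = {}
    factors = {}
    view_rank = min(2, latent_dim)
    for v in schema.views:
        nf = len(view_feats[v])
        plane = np.linalg.qr(rng.normal(size=(latent_dim, view_rank)))[0].T
        loadings = rng.normal(size=(nf, view_rank))
        maps[v] = loadings @ plane
        factors[v] = factor_sd * rng.normal(size=nf)

    rows_ids, rows_feat, latents = [], [], []
    n_lesions = _truncated_poisson(rng, LESION_RATE, n_patients)
    for i in range(n_patients):
        spec = DEFAULT_ARCHETYPES[truth[i]]
        center = center_sd * rng.normal(size=latent_dim)
        z = center + _archetype_positions(spec, int(n_lesions[i]), latent_dim, rng)
        vol = np.round(rng.lognormal(mean=0.5, sigma=0.8, size=len(z)), 3)
        view_shift = {v: rng.normal() for v in schema.views}  # per patient
        for j in range(len(z)):
            x = np.empty(len(feat_names))
            pos = 0
            for v in schema.views:
                nf = len(view_feats[v])
                x[pos:pos + nf] = (
                    maps[v] @ z[j]
                    + factors[v] * view_shift[v]
                    + noise_sd * rng.normal(size=nf)
                )
                pos += nf
            rows_ids.append((f"P{i:03d}", f"L{j:02d}", vol[j]))
            rows_feat.append(x)
            latents.append(z[j])

    ids = pd.DataFrame(rows_ids, columns=["patient_id", "lesion_id", "volume_ml"])
    feats = pd.DataFrame(np.array(rows_feat), columns=feat_names)
    if missing_rate > 0:
        mask = rng.random(feats.shape) < missing_rate
        feats = feats.mask(mask)
    table = RadiomicTable(ids["patient_id"], ids["lesion_id"], ids["volume_ml"], feats)
    truth_s = pd.Series(truth, index=[f"P{i:03d}" for i in range(n_patients)], name="archetype")
    latent_df = pd.DataFrame(np.array(latents))
    latent_df.insert(0, "patient_id", ids["patient_id"].values)
    return SyntheticCohort(table, truth_s, schema, seed, latent=latent_df)


def simulate_clinical(
    truth: pd.Series,
    effect_spec: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    censor_horizon: float = 24.0,
) -> pd.DataFrame:
    """Per-patient clinical covariates with declared group effects.

    ``effect_spec[name]`` may give ``psa_shift`` / ``gleason_shift``
    (location shifts in SD units), ``response_rate`` (hazard scale of the
    exponential time to therapy response) and ``skeleton_rate``.  Zero
    effects produce an exchangeable null table for calibration studies.
    """
    effect_spec = effect_spec or {}
    rng = np.random.default_rng(seed)
    rows = []
    for pid, name in truth.items():
        eff = effect_spec.get(name, {})
        psa = 10.0 * np.exp(0.5 * rng.normal()) + eff.get("psa_shift", 0.0)
        rate = eff.get("response_rate", 0.1)
        t_event = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        event = t_event <= censor_horizon
        rows.append({
            "patient_id": pid,
            "gleason": int(np.clip(round(7 + eff.get("gleason_shift", 0.0) + rng.normal()), 6, 10)),
            "psa": psa,
            "delta_psa_1_0": rng.normal(eff.get("dpsa_shift", 0.0), 1.0),
            "delta_psa_2_0": rng.normal(eff.get("dpsa_shift", 0.0), 1.0),
            "total_volume_ml": float(np.exp(rng.normal(1.5, 0.7))),
            "skeleton": int(rng.random() < eff.get("skeleton_rate", 0.4)),
            "ongoing_therapy": int(rng.random() < 0.5),
            "combined_therapy": int(rng.random() < 0.3),
            "therapy_response": int(event),
            "time_to_response": float(min(t_event, censor_horizon)),
        })
    return pd.DataFrame(rows).set_index("patient_id")


def random_merge_tree(
    n_leaves: int,
    weight_law=None,
    seed: int | np.random.Generator = 0,
) -> MergeTree:
    """Uniformly random agglomeration topology with positive edge weights.

    ``weight_law(rng)`` draws one positive height increment (default
    Exponential(1)).  Used as a fixture generator for metric-property
    checks; outputs always satisfy the merge-tree invariants.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if weight_law is None:
        def weight_law(r):  # noqa: ANN001 - simple default
            return float(r.exponential(1.0)) + 1e-6
    if n_leaves < 1:
        raise ConfigurationError("n_leaves must be >= 1")
    if n_leaves == 1:
        return MergeTree(np.array([-1]), np.array([0.0]), ["L0"])
    n_total = 2 * n_leaves - 1
    parent = -np.ones(n_total, dtype=np.int64)
    height = np.zeros(n_total)
    active = list(range(n_leaves))
    nxt = n_leaves
    for _ in range(n_leaves - 1):
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        height[nxt] = max(height[a], height[b]) + weight_law(rng)
        active = [v for v in active if v not in (a, b)] + [nxt]
        nxt += 1
    labels = [f"L{i}" for i in range(n_leaves)] + [None] * (n_leaves - 1)
    return MergeTree(parent, height, labels)
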