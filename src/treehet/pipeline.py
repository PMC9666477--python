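"""End-to-end pipeline: feature table -> trees -> distances -> strata.

The configuration defaults reproduce the reference protocol: median
imputation, Z-normalization, view-aware PCA with 2 components per view,
average linkage within patients, global height rescaling, Beta(2.5, 15)
threshold measure, exact integration, ward linkage between patients with
k selected over [2, 5].  All randomness flows from one master seed and a
run manifest (config, seed, versions, warnings) is written next to the
outputs, so identical manifests imply identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .mergetree import average_linkage_dendrogram, lesion_distance_matrix, \
    patient_point_cloud, rescale_heights, to_newick
from .preprocess import ViewSchema, default_schema, impute_missing, \
    read_feature_table, view_aware_pca, z_normalize
from .pruned import Measure, cohort_distance_matrix
from .stratify import baseline_biggest_lesion, baseline_mean_vector, \
    characterize_clusters, compare_partitions, ward_cluster

__all__ = ["PipelineConfig", "run_pipeline"]

_LINKAGES = ("single", "complete", "average", "weighted", "ward")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    feature_table: str
    output_dir: str
    schema_file: str | None = None
    clinical_table: str | None = None
    imputation: str = "median"
    k_per_view: int = 2
    within_linkage: str = "average"
    between_linkage: str = "ward"
    rescale_mode: str = "global"
    mu: dict = field(default_factory=lambda: {"family": "beta", "alpha": 2.5, "beta": 15.0})
    integration_mode: str = "exact"
    k_range: tuple[int, int] = (2, 5)
    response_column: str | None = "therapy_response"
    alpha: float = 0.1
    seed: int = 0
    solver: str = "dp"

    def validate(self) -> None:
        if self.within_linkage not in _LINKAGES:
            raise ConfigurationError(f"unknown within-patient linkage {self.within_linkage!r}")
        if self.between_linkage not in _LINKAGES:
            raise ConfigurationError(f"unknown between-patient linkage {self.between_linkage!r}")
        if self.rescale_mode not in ("global", "per_tree"):
            raise ConfigurationError(f"unknown rescale mode {self.rescale_mode!r}")
        if self.imputation not in ("median", "mean"):
            raise ConfigurationError(f"unknown imputation {self.imputation!r}")
        if self.integration_mode not in ("exact", "grid"):
            raise ConfigurationError(f"unknown integration mode {self.integration_mode!r}")
        kmin, kmax = self.k_range
        if not (2 <= kmin <= kmax):
            raise ConfigurationError(f"invalid k range {self.k_range!r}")
        Measure.from_config(self.mu)  # raises on a bad measure spec

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        cfg.k_range = tuple(cfg.k_range)
        return cfg

    def manifest(self) -> dict:
        cfg = asdict(self)
        digest = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
        return {"config": cfg, "config_hash": digest, "treehet_version": "0.1.0",
                "numpy_version": np.__version__}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and persist every intermediate artifact.

    Returns a dict with the in-memory artifacts (reduced matrix, trees,
    distance matrix, clustering result, baselines, optional report).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    collected: list[str] = []

    def record_warnings(ws):
        collected.extend(str(w.message) for w in ws)

    schema = ViewSchema.from_file(config.schema_file) if config.schema_file else default_schema()
    table = read_feature_table(config.feature_table, schema)
    with warnings.catch_warnings(record=True) as ws:
        warnings.simplefilter("always")
        table = z_normalize(impute_missing(table, config.imputation))
        reduced = view_aware_pca(table, schema, config.k_per_view)
    record_warnings(ws)
    reduced.to_csv(out / "reduced.csv")

    patients = reduced.patients
    trees = []
    for pid in patients:
        cloud = patient_point_cloud(reduced, pid)
        trees.append(average_linkage_dendrogram(lesion_distance_matrix(cloud),
                                                labels=cloud.lesion_ids))
    with warnings.catch_warnings(record=True) as ws:
        warnings.simplefilter("always")
        scaled = rescale_heights(trees, mode=config.rescale_mode)
    record_warnings(ws)
    tree_dir = out / "trees"
    tree_dir.mkdir(exist_ok=True)
    for pid, t in zip(patients, scaled):
        (tree_dir / f"{pid}.nwk").write_text(to_newick(t) + "\n")

    mu = Measure.from_config(config.mu)
    D = cohort_distance_matrix(scaled, mu, mode=config.integration_mode,
                               rng_seed=config.seed, solver=config.solver,
                               patient_ids=patients)
    D.to_csv(out / "distance_matrix.csv")

    clinical = None
    response = None
    if config.clinical_table:
        clinical = pd.read_csv(config.clinical_table).set_index("patient_id").loc[patients]
        if config.response_column and config.response_column in clinical.columns:
            response = clinical[config.response_column].to_numpy()

    result = ward_cluster(D, k_range=config.k_range, response=response,
                          linkage_name=config.between_linkage)
    result.as_series().to_csv(out / "labels.csv")
    result.trace.to_csv(out / "selection_trace.csv", index=False)

    volumes = table.volume_ml.reset_index(drop=True)
    baselines = {}
    if volumes.notna().all():
        baselines["biggest_lesion"] = baseline_biggest_lesion(reduced, volumes,
                                                              config.k_range, response)
    baselines["mean_vector"] = baseline_mean_vector(reduced, config.k_range, response)
    base_rows = [
        {"baseline": name, "k": b.k, "silhouette": b.silhouette,
         "rand_vs_tree": compare_partitions(result.labels, b.labels)}
        for name, b in baselines.items()
    ]
    pd.DataFrame(base_rows).to_csv(out / "baselines.csv", index=False)

    report = None
    if clinical is not None:
        drop = [c for c in (config.response_column, "time_to_response") if c in clinical]
        report = characterize_clusters(result.labels, clinical.drop(columns=drop),
                                       alpha=config.alpha)
        report.to_csv(out / "characterization.csv", index=False)

    manifest = config.manifest() | {"n_patients": len(patients), "warnings": collected}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return {"reduced": reduced, "trees": scaled, "distance_matrix": D,
            "clustering": result, "baselines": baselines, "report": report,
            "manifest": manifest}
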