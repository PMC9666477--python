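"""Radiomic feature tables and view-aware PCA.

Lesion-level radiomic descriptors divide into six semantic groups
("views"): first-order statistics of the grey-level distribution, shape
descriptors, and the four texture-matrix families GLCM, GLRLM, GLZLM and
NGLDM.  Features within a view are built from the same texture matrix and
are strongly collinear, so dimensionality is reduced *per view*: after
imputation and Z-normalization a PCA is fitted on each view's sub-matrix
and the top two components are retained, giving every lesion a
12-dimensional vector (2 components x 6 views) with balanced importance
across views.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError, FormatError, IntegrityError

__all__ = [
    "ViewSchema",
    "RadiomicTable",
    "ReducedMatrix",
    "default_schema",
    "read_feature_table",
    "impute_missing",
    "z_normalize",
    "view_aware_pca",
]

ID_COLUMNS = ("patient_id", "lesion_id")
VOLUME_COLUMN = "volume_ml"

_DEFAULT_VIEW_FEATURES = {
    "firstorder": [
        "firstorder_mean", "firstorder_sd", "firstorder_skewness",
        "firstorder_kurtosis", "firstorder_entropy", "firstorder_energy",
        "firstorder_min", "firstorder_max",
    ],
    "shape": [
        "shape_sphericity", "shape_compacity", "shape_surface_mm2",
        "shape_elongation",
    ],
    "glcm": [
        "glcm_homogeneity", "glcm_energy", "glcm_contrast",
        "glcm_correlation", "glcm_entropy", "glcm_dissimilarity",
        "glcm_autocorrelation",
    ],
    "glrlm": [
        "glrlm_sre", "glrlm_lre", "glrlm_lgre", "glrlm_hgre", "glrlm_srlge",
        "glrlm_srhge", "glrlm_lrlge", "glrlm_lrhge", "glrlm_glnu",
        "glrlm_rlnu", "glrlm_rp",
    ],
    "glzlm": [
        "glzlm_sze", "glzlm_lze", "glzlm_lgze", "glzlm_hgze",
        "glzlm_zlnu", "glzlm_glnu", "glzlm_zp",
    ],
    "ngldm": ["ngldm_coarseness", "ngldm_contrast", "ngldm_busyness"],
}


@dataclass
class ViewSchema:
    """Assignment of every radiomic feature to exactly one semantic view."""

    view_of_feature: dict[str, str]
    views: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for v in self.view_of_feature.values():
            if v not in seen:
                seen.append(v)
        if not self.views:
            self.views = seen
        missing = set(self.view_of_feature.values()) - set(self.views)
        if missing:
            raise ConfigurationError(f"features reference undeclared views: {sorted(missing)}")

    @property
    def features(self) -> list[str]:
        return list(self.view_of_feature)

    def features_of_view(self, view: str) -> list[str]:
        return [f for f, v in self.view_of_feature.items() if v == view]

    @classmethod
    def from_file(cls, path: str | Path) -> "ViewSchema":
        path = Path(path)
        text = path.read_text()
        mapping = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(mapping, dict):
            raise FormatError(f"schema file {path} must map feature -> view")
        return cls(dict(mapping))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.view_of_feature, indent=1))
        else:
            path.write_text(yaml.safe_dump(self.view_of_feature, sort_keys=False))


def default_schema() -> ViewSchema:
    """The six-view, forty-feature LifeX-style default schema."""
    mapping = {f: v for v, feats in _DEFAULT_VIEW_FEATURES.items() for f in feats}
    return ViewSchema(mapping, list(_DEFAULT_VIEW_FEATURES))


@dataclass
class RadiomicTable:
    """Lesion-by-feature matrix with patient/lesion keys and volumes."""

    patient_id: pd.Series
    lesion_id: pd.Series
    volume_ml: pd.Series
    features: pd.DataFrame

    def __post_init__(self) -> None:
        keys = pd.MultiIndex.from_arrays([self.patient_id, self.lesion_id])
        if keys.duplicated().any():
            dup = keys[keys.duplicated()][0]
            raise IntegrityError(f"duplicate (patient_id, lesion_id) key: {tuple(dup)}")
        vols = self.volume_ml.dropna()
        if (vols < 0).any():
            raise DataError("lesion volumes must be nonnegative")

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @property
    def n_lesions(self) -> int:
        return self.features.shape[0]

    def copy(self) -> "RadiomicTable":
        return RadiomicTable(
            self.patient_id.copy(), self.lesion_id.copy(),
            self.volume_ml.copy(), self.features.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "patient_id": self.patient_id.values,
            "lesion_id": self.lesion_id.values,
            VOLUME_COLUMN: self.volume_ml.values,
        })
        return pd.concat([out, self.features.reset_index(drop=True)], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ReducedMatrix:
    """Per-lesion scores after view-aware PCA: 2 columns per view."""

    patient_id: pd.Series
    lesion_id: pd.Series
    scores: np.ndarray
    columns: list[str]
    explained_variance: dict[str, np.ndarray]
    loadings: dict[str, pd.DataFrame]

    @property
    def n_lesions(self) -> int:
        return self.scores.shape[0]

    @property
    def patients(self) -> list:
        return list(pd.unique(self.patient_id))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.scores, columns=self.columns)
        out.insert(0, "lesion_id", self.lesion_id.values)
        out.insert(0, "patient_id", self.patient_id.values)
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_feature_table(path: str | Path, schema: ViewSchema) -> RadiomicTable:
    """Read a lesion-level CSV with header ``patient_id,lesion_id,volume_ml,<features>``.

    Non-numeric feature cells become missing values; volumes are optional.
    """
    df = pd.read_csv(path)
    for col in ID_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"feature table is missing mandatory column {col!r}")
    absent = [f for f in schema.features if f not in df.columns]
    if absent:
        raise FormatError(f"feature table is missing schema feature {absent[0]!r}")
    vols = (
        pd.to_numeric(df[VOLUME_COLUMN], errors="coerce")
        if VOLUME_COLUMN in df.columns
        else pd.Series(np.nan, index=df.index)
    )
    feats = df[schema.features].apply(pd.to_numeric, errors="coerce")
    return RadiomicTable(df["patient_id"], df["lesion_id"], vols, feats)


def impute_missing(table: RadiomicTable, strategy: str = "median") -> RadiomicTable:
    """Fill missing feature cells with the per-feature median (or mean)."""
    if strategy not in ("median", "mean"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    feats = table.features.copy()
    all_missing = feats.columns[feats.isna().all()]
    if len(all_missing):
        raise DataError(f"feature {all_missing[0]!r} has no observed values to impute from")
    fill = feats.median() if strategy == "median" else feats.mean()
    out = table.copy()
    out.features = feats.fillna(fill)
    return out


def z_normalize(table: RadiomicTable) -> RadiomicTable:
    """Standardize each feature to mean 0, sample SD 1 (denominator n-1).

    Constant features carry no information and are dropped with a warning
    (real radiomic exports do contain them).
    """
    feats = table.features
    if feats.isna().any().any():
        raise DataError("impute missing values before normalization")
    sd = feats.std(ddof=1)
    constant = feats.columns[(sd == 0) | sd.isna()]
    if len(constant):
        warnings.warn(f"dropping constant feature(s): {list(constant)}", stacklevel=2)
        feats = feats.drop(columns=constant)
        sd = sd.drop(constant)
    out = table.copy()
    out.features = (feats - feats.mean()) / sd
    return out


def _pca_scores(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered PCA with a fixed sign convention.

    The sign of each component is chosen so that its loading of largest
    absolute value is positive, making the reduction deterministic.
    """
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return Xc @ Vt[:k].T, frac[:k], Vt[:k]


def view_aware_pca(
    table: RadiomicTable, schema: ViewSchema, k_per_view: int = 2
) -> ReducedMatrix:
    """Per-view PCA keeping ``k_per_view`` components from each view.

    The PCA of every view is fitted on the pooled lesions of the whole
    cohort, so scores of different patients live in the same reduced space.
    """
    if table.n_lesions < 2:
        raise DataError("view-aware PCA needs at least 2 lesions")
    if table.features.isna().any().any():
        raise DataError("impute and normalize the table before PCA")
    blocks, columns = [], []
    explained: dict[str, np.ndarray] = {}
    loadings: dict[str, pd.DataFrame] = {}
    for view in schema.views:
        feats = [f for f in schema.features_of_view(view) if f in table.features.columns]
        X = table.features[feats].to_numpy(dtype=float)
        usable = sum(np.std(X[:, j]) > 0 for j in range(X.shape[1]))
        if usable < k_per_view:
            raise ConfigurationError(
                f"view {view!r} has {usable} non-constant feature(s), "
                f"fewer than k_per_view={k_per_view}"
            )
        scores, frac, load = _pca_scores(X, k_per_view)
        blocks.append(scores)
        columns.extend(f"{view}_pc{j + 1}" for j in range(k_per_view))
        explained[view] = frac
        loadings[view] = pd.DataFrame(load, columns=feats,
                                      index=[f"pc{j + 1}" for j in range(k_per_view)])
    return ReducedMatrix(
        table.patient_id.reset_index(drop=True),
        table.lesion_id.reset_index(drop=True),
        np.hstack(blocks), columns, explained, loadings,
    )
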