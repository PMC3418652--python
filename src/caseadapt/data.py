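"""Domain types and delimited-text I/O for case libraries.

A *case* is one lesion: a real-valued feature vector (nine image-derived
features in the motivating CADx application), a binary pathology label
(1 = malignant), and an opaque identifier.  A :class:`CaseLibrary` is an
ordered collection of cases playing one of three roles: the training set
for the baseline classifier, the held-out test set, or the reference
library that similar cases are retrieved from.

Features are z-scored with statistics fitted on the training split only
(sample standard deviation, ``ddof=1``); Euclidean retrieval distances and
the similarity bandwidth are computed in this standardized space.  The
classifier operates on *augmented* vectors whose leading element is the
constant 1, so the bias term is absorbed into the discriminant vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CaseRecord",
    "CaseLibrary",
    "Standardizer",
    "SchemaError",
    "LabelError",
    "DegenerateFeatureError",
    "read_library",
    "write_library",
    "augment",
    "fit_standardizer",
]


class SchemaError(ValueError):
    """Raised when a CSV file does not match the declared column schema."""


class LabelError(ValueError):
    """Raised when the label column cannot be mapped onto {0, 1}."""


class DegenerateFeatureError(ValueError):
    """Raised when a feature has zero variance on the fitting split."""


@dataclass(frozen=True)
class CaseRecord:
    """One lesion: identifier, feature vector and binary label (1 = malignant)."""

    id: str
    features: np.ndarray
    label: int

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        if feats.ndim != 1:
            raise ValueError("features must be a 1-D vector")
        if not np.all(np.isfinite(feats)):
            raise ValueError(f"case {self.id!r}: non-finite feature value")
        if self.label not in (0, 1):
            raise LabelError(f"case {self.id!r}: label must be 0 or 1, got {self.label!r}")
        object.__setattr__(self, "features", feats)


class CaseLibrary:
    """Ordered collection of :class:`CaseRecord` with a role tag.

    Parameters
    ----------
    records : sequence of CaseRecord
        All records must share the same feature dimension; ids must be
        unique within the library.
    role : str
        One of ``{"train", "test", "retrieval"}`` (free-form tags are
        accepted but these are the conventional roles).
    """

    def __init__(self, records: Sequence[CaseRecord], role: str = "train") -> None:
        records = list(records)
        if records:
            d = records[0].features.shape[0]
            for r in records:
                if r.features.shape[0] != d:
                    raise ValueError(
                        f"inconsistent feature dimension: {r.features.shape[0]} != {d}"
                    )
            ids = [r.id for r in records]
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate case ids within a library")
        self.records = records
        self.role = role

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> CaseRecord:
        return self.records[i]

    @property
    def n_features(self) -> int:
        if not self.records:
            raise ValueError("empty library has no feature dimension")
        return self.records[0].features.shape[0]

    @property
    def features(self) -> np.ndarray:
        """(n_cases, d) feature matrix in library order."""
        return np.array([r.features for r in self.records], dtype=float)

    @property
    def labels(self) -> np.ndarray:
        """(n_cases,) integer label vector in library order."""
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        ids: Sequence[str] | None = None,
        role: str = "train",
    ) -> "CaseLibrary":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if ids is None:
            ids = [f"{role}-{i}" for i in range(X.shape[0])]
        recs = [CaseRecord(str(i), x, int(lab)) for i, x, lab in zip(ids, X, y)]
        return cls(recs, role=role)


@dataclass
class Standardizer:
    """Per-feature z-score transform fitted on the training split.

    Uses the sample standard deviation (``ddof=1``).  The same fitted
    transform is applied to the test and retrieval libraries so that all
    splits share one feature space.
    """

    mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            raise DegenerateFeatureError("all scales must be strictly positive")

    @property
    def n_features(self) -> int:
        return self.mean.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[-1]}")
        return (X - self.mean) / self.scale

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        if Z.shape[-1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {Z.shape[-1]}")
        return Z * self.scale + self.mean

    @classmethod
    def identity(cls, d: int) -> "Standardizer":
        return cls(mean=np.zeros(d), scale=np.ones(d))

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(mean=np.asarray(d["mean"]), scale=np.asarray(d["scale"]))


def fit_standardizer(lib: CaseLibrary) -> Standardizer:
    """Fit a z-score :class:`Standardizer` on a library.

    Raises
    ------
    DegenerateFeatureError
        If any feature column has zero variance, naming the column.
    ValueError
        If the library has fewer than two records.
    """
    if len(lib) < 2:
        raise ValueError("need at least 2 records to fit a standardizer")
    X = lib.features
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(scale == 0)
    if bad.size:
        raise DegenerateFeatureError(
            f"feature column(s) {bad.tolist()} have zero variance"
        )
    return Standardizer(mean=mean, scale=scale)


def augment(features: np.ndarray, std: Standardizer | None = None) -> np.ndarray:
    """Standardize a feature vector (or matrix) and prepend the constant 1.

    The returned vector has length ``d + 1`` with element 0 exactly 1, so a
    discriminant vector ``w`` of length ``d + 1`` carries its bias in
    ``w[0]``.
    """
    features = np.asarray(features, dtype=float)
    if std is not None:
        features = std.transform(features)
    if features.ndim == 1:
        return np.concatenate(([1.0], features))
    ones = np.ones((features.shape[0], 1))
    return np.hstack([ones, features])


# ---------------------------------------------------------------------------
# CSV I/O

DEFAULT_SCHEMA = {"id": "id", "label": "label", "features": None}


def read_library(
    path,
    schema: dict | None = None,
    role: str = "train",
) -> CaseLibrary:
    """Read a case library from a comma-separated text file.

    Parameters
    ----------
    path : path-like
        CSV file with a header row, '.' decimal mark, UTF-8.
    schema : dict, optional
        Keys ``id`` (id column name; optional — row index used if absent
        from the file), ``label`` (label column name), ``features`` (list
        of feature column names, or None meaning every remaining column),
        and optionally ``label_map`` mapping the two raw label values onto
        0/1.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    label_col = schema["label"]
    if label_col not in df.columns:
        raise SchemaError(f"label column {label_col!r} not found in {path}")
    id_col = schema["id"]
    feat_cols = schema["features"]
    if feat_cols is None:
        feat_cols = [c for c in df.columns if c not in (label_col, id_col)]
    missing = [c for c in feat_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing feature column(s) {missing} in {path}")

    raw_labels = df[label_col]
    distinct = pd.unique(raw_labels)
    if len(distinct) > 2:
        raise LabelError(
            f"label column {label_col!r} has {len(distinct)} distinct values; expected 2"
        )
    label_map = schema.get("label_map")
    if label_map is None:
        try:
            numeric = {int(v) for v in distinct}
        except (TypeError, ValueError):
            numeric = set()
        if numeric <= {0, 1}:
            label_map = {v: int(v) for v in distinct}
        else:
            raise LabelError(
                f"label values {sorted(map(str, distinct))} are not 0/1; provide a label_map"
            )
    labels = raw_labels.map(label_map)
    if labels.isna().any():
        raise LabelError("label_map does not cover all observed label values")

    feats = df[feat_cols]
    for col in feat_cols:
        coerced = pd.to_numeric(feats[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & feats[col].notna())
        if bad.size or coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise SchemaError(f"non-numeric feature value in column {col!r}, row {row}")
    X = feats.to_numpy(dtype=float)

    if id_col is not None and id_col in df.columns:
        ids = df[id_col].astype(str).tolist()
    else:
        ids = [str(i) for i in range(len(df))]
    recs = [
        CaseRecord(ids[i], X[i], int(labels.iloc[i])) for i in range(len(df))
    ]
    return CaseLibrary(recs, role=role)


def write_library(lib: CaseLibrary, path, schema: dict | None = None) -> None:
    """Write a library back to CSV (17 significant digits: exact round-trip)."""
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    d = lib.n_features
    feat_cols = schema["features"] or [f"f{k}" for k in range(d)]
    df = pd.DataFrame(lib.features, columns=feat_cols)
    df.insert(0, schema["id"] or "id", lib.ids)
    df[schema["label"]] = lib.labels
    df.to_csv(path, index=False, float_format="%.17g")
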