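"""Multi-label dataset model, tabular I/O, and binary-relevance decomposition.

A multi-label dataset ``D = {(x_i, Y_i)}`` pairs each of N feature vectors
with a value for every label in ``L = {y_1 .. y_q}``.  Binary labels carry a
designated "present" class, so ``Y_i`` can equivalently be read as the subset
of L present on sample i.  The binary-relevance (BR) transformation turns D
into q single-target datasets ``D_{y_j}``, one per label, each keeping the
full feature block and all N rows — the per-client view used by the
federated learner.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "LabelSpec",
    "MultiLabelDataset",
    "SingleTargetDataset",
    "FeatureSummary",
    "CsvDialect",
    "read_csv_dataset",
    "decompose",
    "summarize_feature",
]

FEATURE_KINDS = ("numeric", "nominal", "ordinal")
ROLES = ("input", "identifier", "excluded", "target")


@dataclass(frozen=True)
class FeatureSpec:
    """Schema entry for one feature column.

    ``categories`` is empty for numeric features and holds the declared,
    ordered category strings for nominal/ordinal ones (order is meaningful
    for ordinal features: it is their rank order).
    """

    name: str
    kind: str = "numeric"
    categories: tuple[str, ...] = ()
    role: str = "input"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name!r}")
        if self.kind == "numeric" and self.categories:
            raise ValueError(f"numeric feature {self.name!r} must not declare categories")
        if self.kind in ("nominal", "ordinal"):
            if not self.categories:
                raise ValueError(f"{self.kind} feature {self.name!r} needs categories")
            if len(set(self.categories)) != len(self.categories):
                raise ValueError(f"duplicate categories on feature {self.name!r}")


@dataclass(frozen=True)
class LabelSpec:
    """Schema entry for one label y_j.

    ``positive`` designates the "present" class of a binary label; it is
    None for multi-class labels.
    """

    name: str
    classes: tuple[str, ...]
    positive: str | None = None

    def __post_init__(self) -> None:
        if len(self.classes) < 2 or len(set(self.classes)) != len(self.classes):
            raise ValueError(f"label {self.name!r} needs >=2 distinct classes")
        if self.is_binary:
            pos = self.positive if self.positive is not None else self.classes[-1]
            if pos not in self.classes:
                raise ValueError(f"positive class {pos!r} not among {self.classes}")
            object.__setattr__(self, "positive", pos)
        elif self.positive is not None:
            raise ValueError(f"multi-class label {self.name!r} cannot designate a positive class")

    @property
    def is_binary(self) -> bool:
        return len(self.classes) == 2


@dataclass
class MultiLabelDataset:
    """N rows x (K input features + q labels), plus retained metadata columns.

    ``X`` holds only input-role feature columns (numeric as float with NaN
    for missing, nominal/ordinal as strings with None/NaN for missing);
    ``Y`` holds one string column per label with no missing values.
    Identifier/excluded columns are kept in ``extras`` and never reach a
    learner.
    """

    name: str
    features: tuple[FeatureSpec, ...]
    labels: tuple[LabelSpec, ...]
    X: pd.DataFrame
    Y: pd.DataFrame
    extras: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        self.labels = tuple(self.labels)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.n_samples < 1 or self.n_features < 1 or self.n_labels < 1:
            raise ValueError("dataset needs N >= 1, K >= 1, q >= 1")
        for spec in self.features:
            if spec.role != "input":
                raise ValueError(f"non-input feature {spec.name!r} in feature list")
        if list(self.X.columns) != [f.name for f in self.features]:
            raise ValueError("X columns do not match feature schema order")
        if list(self.Y.columns) != [l.name for l in self.labels]:
            raise ValueError("Y columns do not match label schema order")
        if len(self.X) != len(self.Y):
            raise ValueError("feature and label blocks disagree on N")
        for lab in self.labels:
            col = self.Y[lab.name]
            if col.isna().any():
                raise ValueError(f"label {lab.name!r} has missing values")
            bad = set(col.unique()) - set(lab.classes)
            if bad:
                raise ValueError(f"label {lab.name!r} has undeclared values {sorted(bad)}")
        for spec in self.features:
            if spec.kind in ("nominal", "ordinal"):
                col = self.X[spec.name].dropna()
                bad = set(col.unique()) - set(spec.categories)
                if bad:
                    raise ValueError(
                        f"feature {spec.name!r} has undeclared categories {sorted(bad)}"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def feature(self, name: str) -> FeatureSpec:
        for spec in self.features:
            if spec.name == name:
                return spec
        raise KeyError(f"unknown feature {name!r}")

    def label_sets(self) -> list[set[str]]:
        """Per-row subset Y_i of L (binary labels only)."""
        if not all(l.is_binary for l in self.labels):
            raise ValueError("label subsets are defined for all-binary label schemas")
        out: list[set[str]] = []
        for _, row in self.Y.iterrows():
            out.append({l.name for l in self.labels if row[l.name] == l.positive})
        return out


@dataclass
class SingleTargetDataset:
    """One client's local view: the full feature block plus a single target.

    In ``strict_binary`` mode the target is the integer 1 when the source
    label is present on the row and 0 otherwise; in ``per_label`` mode it is
    the label's class value itself.  Row count and feature schema are always
    identical to the parent dataset's.
    """

    source_label: LabelSpec
    features: tuple[FeatureSpec, ...]
    X: pd.DataFrame
    y: pd.Series
    mode: str = "strict_binary"

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        if self.mode not in ("strict_binary", "per_label"):
            raise ValueError(f"unknown decomposition mode {self.mode!r}")
        if len(self.X) != len(self.y):
            raise ValueError("feature block and target disagree on N")
        if self.mode == "strict_binary":
            vals = set(pd.unique(self.y))
            if not vals <= {0, 1}:
                raise ValueError("strict_binary targets must be in {0, 1}")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def target_classes(self) -> tuple[str, ...]:
        """Class inventory the learner should use, in declaration order."""
        if self.mode == "strict_binary":
            return ("0", "1")
        return self.source_label.classes

    def target_codes(self) -> np.ndarray:
        """Target as integer codes into :meth:`target_classes`."""
        if self.mode == "strict_binary":
            return self.y.to_numpy(dtype=np.int64)
        lookup = {c: i for i, c in enumerate(self.source_label.classes)}
        return np.array([lookup[v] for v in self.y], dtype=np.int64)


@dataclass(frozen=True)
class FeatureSummary:
    """min/mean/max/mode/std digest of a numeric feature (mode is None when
    no value repeats, printed as "No" in tabular summaries)."""

    name: str
    min: float
    max: float
    mean: float
    mode: float | None
    std: float
    n_missing: int


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CsvDialect:
    """Delimited-text conventions; defaults ingest the UCI Amphibians
    distribution unmodified (semicolon-separated, one header row, empty
    field = missing)."""

    delimiter: str = ";"
    header_rows: int = 1
    missing: str = ""
    quotechar: str = '"'


def _specs_from_schema(schema: Mapping) -> tuple[list[dict], str]:
    name = str(schema.get("name", "dataset"))
    columns = schema.get("columns")
    if not columns:
        raise ValueError("schema must list 'columns'")
    out = []
    for col in columns:
        if "name" not in col:
            raise ValueError("every schema column needs a 'name'")
        out.append(dict(col))
    return out, name


def read_csv_dataset(
    path,
    schema: Mapping,
    dialect: CsvDialect | None = None,
) -> MultiLabelDataset:
    """Read a delimited text file into a :class:`MultiLabelDataset`.

    ``schema`` is a mapping with a ``columns`` list; each entry gives
    ``name``, optional ``kind`` (default numeric for non-targets), ``role``
    (default input; ``target`` marks a label), ``categories`` / ``classes``
    and, for binary labels, ``positive``.  Missingness is allowed in input
    features only.
    """
    dialect = dialect or CsvDialect()
    columns, ds_name = _specs_from_schema(schema)

    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter, quotechar=dialect.quotechar)
        rows = list(reader)
    if dialect.header_rows:
        header = rows[dialect.header_rows - 1]
        body = rows[dialect.header_rows :]
    else:
        header = [c["name"] for c in columns]
        body = rows
    header = [h.strip() for h in header]

    width = len(header)
    for i, r in enumerate(body):
        if len(r) != width:
            raise ValueError(f"ragged row {i}: {len(r)} fields, expected {width}")

    declared = {c["name"] for c in columns}
    missing_cols = declared - set(header)
    if missing_cols:
        raise ValueError(f"schema columns absent from file: {sorted(missing_cols)}")

    frame = pd.DataFrame(body, columns=header, dtype=object)
    return _assemble(frame, columns, ds_name, missing_marker=dialect.missing)


def _assemble(
    frame: pd.DataFrame,
    columns: Sequence[Mapping],
    ds_name: str,
    missing_marker: str,
) -> MultiLabelDataset:
    """Build a dataset from an all-string frame plus per-column schema."""
    feats: list[FeatureSpec] = []
    labels: list[LabelSpec] = []
    xcols: dict[str, object] = {}
    ycols: dict[str, object] = {}
    extra_names: list[str] = []

    for col in columns:
        name = col["name"]
        role = col.get("role", "input")
        raw = frame[name].astype(object).map(lambda v: None if v is None else str(v).strip())
        is_missing = raw.map(lambda v: v is None or v == missing_marker)
        if role == "target":
            if bool(is_missing.any()):
                raise ValueError(f"label {name!r} has missing values")
            values = raw.astype(str)
            classes = col.get("classes")
            if classes is None:
                classes = sorted(values.unique())
            classes = tuple(str(c) for c in classes)
            bad = set(values.unique()) - set(classes)
            if bad:
                raise ValueError(f"label {name!r} value(s) {sorted(bad)} not in declared classes")
            positive = col.get("positive")
            labels.append(LabelSpec(name, classes, None if len(classes) != 2 else (
                str(positive) if positive is not None else None)))
            ycols[name] = values
            continue
        if role in ("identifier", "excluded"):
            extra_names.append(name)
            continue
        kind = col.get("kind", "numeric")
        if kind == "numeric":
            vals = pd.to_numeric(raw.where(~is_missing, other=None))
            xcols[name] = vals.astype(float)
            feats.append(FeatureSpec(name, "numeric", (), "input"))
        else:
            cats = col.get("categories")
            present = raw[~is_missing]
            if cats is None:
                cats = sorted(present.unique())
            cats = tuple(str(c) for c in cats)
            xcols[name] = raw.where(~is_missing, other=None)
            feats.append(FeatureSpec(name, kind, cats, "input"))

    if not labels:
        raise ValueError("schema declares no target columns")
    X = pd.DataFrame({f.name: xcols[f.name] for f in feats})
    Y = pd.DataFrame(ycols)[[l.name for l in labels]]
    extras = frame[extra_names].copy() if extra_names else None
    return MultiLabelDataset(ds_name, tuple(feats), tuple(labels), X, Y, extras)


# ---------------------------------------------------------------------------
# Binary-relevance decomposition
# ---------------------------------------------------------------------------


def decompose(dataset: MultiLabelDataset, mode: str = "strict_binary") -> list[SingleTargetDataset]:
    """Split a multi-label dataset into q single-target datasets, one per
    label, in label declaration order.

    ``strict_binary`` requires every label to be binary and emits 0/1
    targets (1 iff the label's designated positive class is present);
    ``per_label`` keeps each label's class value as the target, which is how
    multi-class labels (e.g. taxonomic family/genus/species) are handled.
    """
    if mode not in ("strict_binary", "per_label"):
        raise ValueError(f"unknown decomposition mode {mode!r}")
    out: list[SingleTargetDataset] = []
    for lab in dataset.labels:
        col = dataset.Y[lab.name]
        if mode == "strict_binary":
            if not lab.is_binary:
                raise ValueError(
                    f"strict_binary decomposition requires binary labels; {lab.name!r} has "
                    f"{len(lab.classes)} classes"
                )
            y = pd.Series((col == lab.positive).astype(int).to_numpy(), name=lab.name)
        else:
            y = pd.Series(col.to_numpy(), name=lab.name)
        out.append(SingleTargetDataset(lab, dataset.features, dataset.X, y, mode))
    return out


# ---------------------------------------------------------------------------
# Feature summaries
# ---------------------------------------------------------------------------


def summarize_feature(dataset: MultiLabelDataset, feature: str) -> FeatureSummary:
    """min/max/mean/mode/std over the non-missing values of a numeric
    feature (std with the n−1 denominator; mode absent when every value is
    unique)."""
    spec = dataset.feature(feature)
    if spec.kind != "numeric":
        raise ValueError(f"feature {feature!r} is not numeric")
    col = dataset.X[feature]
    vals = col.dropna().to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError(f"feature {feature!r} has no non-missing values")
    counts = pd.Series(vals).value_counts()
    mode = float(counts.index[0]) if counts.iloc[0] > 1 else None
    std = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return FeatureSummary(
        name=feature,
        min=float(vals.min()),
        max=float(vals.max()),
        mean=float(vals.mean()),
        mode=mode,
        std=std,
        n_missing=int(col.isna().sum()),
    )
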