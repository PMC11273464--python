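"""Shared fixtures: tiny hand-built datasets and oracle helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fmll.datasets import (
    FeatureSpec,
    LabelSpec,
    MultiLabelDataset,
    SingleTargetDataset,
)


def build_dataset(
    feature_values: dict,
    label_values: dict,
    feature_kinds: dict | None = None,
    label_classes: dict | None = None,
    name: str = "toy",
) -> MultiLabelDataset:
    """Assemble a MultiLabelDataset from plain dicts of column values."""
    feature_kinds = feature_kinds or {}
    label_classes = label_classes or {}
    feats = []
    xcols = {}
    for fname, vals in feature_values.items():
        kind = feature_kinds.get(fname, "numeric")
        if kind == "numeric":
            feats.append(FeatureSpec(fname, "numeric"))
            xcols[fname] = pd.Series([np.nan if v is None else float(v) for v in vals])
        else:
            cats = tuple(sorted({str(v) for v in vals if v is not None}))
            feats.append(FeatureSpec(fname, kind, cats))
            xcols[fname] = pd.Series([None if v is None else str(v) for v in vals], dtype=object)
    labels = []
    ycols = {}
    for lname, vals in label_values.items():
        classes = label_classes.get(lname)
        if classes is None:
            classes = tuple(sorted({str(v) for v in vals}))
        classes = tuple(str(c) for c in classes)
        positive = classes[-1] if len(classes) == 2 else None
        labels.append(LabelSpec(lname, classes, positive))
        ycols[lname] = pd.Series([str(v) for v in vals], dtype=object)
    return MultiLabelDataset(
        name, tuple(feats), tuple(labels), pd.DataFrame(xcols), pd.DataFrame(ycols)
    )


def single_target(
    x: dict, y, classes=("A", "B"), kinds=None, mode="per_label", label_name="target"
) -> SingleTargetDataset:
    """A one-label dataset for exercising the tree learner directly."""
    kinds = kinds or {}
    feats = []
    xcols = {}
    for fname, vals in x.items():
        kind = kinds.get(fname, "numeric")
        if kind == "numeric":
            feats.append(FeatureSpec(fname, "numeric"))
            xcols[fname] = pd.Series([np.nan if v is None else float(v) for v in vals])
        else:
            cats = tuple(sorted({str(v) for v in vals if v is not None}))
            feats.append(FeatureSpec(fname, kind, cats))
            xcols[fname] = pd.Series([None if v is None else str(v) for v in vals], dtype=object)
    classes = tuple(str(c) for c in classes)
    spec = LabelSpec(label_name, classes, classes[-1] if len(classes) == 2 else None)
    if mode == "strict_binary":
        series = pd.Series([int(v) for v in y])
    else:
        series = pd.Series([str(v) for v in y], dtype=object)
    return SingleTargetDataset(spec, tuple(feats), pd.DataFrame(xcols), series, mode)


@pytest.fixture
def toy_multilabel() -> MultiLabelDataset:
    """Three samples over four binary labels: Y1={y2,y4}, Y2={y1,y3,y4},
    Y3={y3} (the classic binary-relevance walk-through)."""
    return build_dataset(
        {"f1": [0.1, 0.2, 0.3], "f2": [1.0, 2.0, 3.0]},
        {
            "y1": ["0", "1", "0"],
            "y2": ["1", "0", "0"],
            "y3": ["0", "1", "1"],
            "y4": ["1", "1", "0"],
        },
        label_classes={k: ("0", "1") for k in ("y1", "y2", "y3", "y4")},
    )


@pytest.fixture
def four_row_part() -> SingleTargetDataset:
    """x = (1,2,3,4) with classes (A,A,B,B): one clean threshold at 2.5."""
    return single_target({"x": [1, 2, 3, 4]}, ["A", "A", "B", "B"])
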