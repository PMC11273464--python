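"""Simulated client/server protocol for federated multi-label learning.

One client per label: client j holds only the binary-relevance view
``D_{y_j}`` of the shared sample space and trains its local REPTree.  The
server receives the fitted models — models are the only payload that
crosses the client boundary, never raw rows — and aggregates them into the
global model ``G``, a pure label-keyed union.  Predicting a label set is
the concatenation of the per-label model outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datasets import LabelSpec, MultiLabelDataset, SingleTargetDataset, decompose
from .reptree import REPTreeConfig, REPTreeModel, fit_reptree

__all__ = ["ClientNode", "GlobalModel", "client_prepare", "client_train", "server_aggregate",
           "predict_label_set", "train_global_model"]


@dataclass
class ClientNode:
    """Client j: its label, its local single-target data, and (after
    training) its local model.  Clients are isolated: no client object ever
    references another client's data or model."""

    index: int
    label: LabelSpec
    local_data: SingleTargetDataset
    local_model: REPTreeModel | None = None

    def __post_init__(self) -> None:
        if self.local_data.source_label.name != self.label.name:
            raise ValueError("client label and local data disagree")


def client_prepare(dataset: MultiLabelDataset, mode: str = "strict_binary") -> list[ClientNode]:
    """Decompose the dataset and hand each label's view to its own client
    (client indices follow label declaration order, 1-based)."""
    parts = decompose(dataset, mode)
    return [
        ClientNode(index=j + 1, label=part.source_label, local_data=part)
        for j, part in enumerate(parts)
    ]


def client_train(client: ClientNode, config: REPTreeConfig | None = None) -> ClientNode:
    """Train the client's local model; returns a new ClientNode, leaving the
    input untouched (clients are trainable in any order with identical
    results — there is no shared mutable state)."""
    model = fit_reptree(client.local_data, config)
    return replace(client, local_model=model)


@dataclass
class GlobalModel:
    """G = union of the q per-label local models, keyed and ordered by the
    source dataset's label order.  Aggregation stores members unchanged."""

    models: dict[str, REPTreeModel]
    label_order: tuple[LabelSpec, ...]

    def __post_init__(self) -> None:
        names = [l.name for l in self.label_order]
        if sorted(self.models) != sorted(names):
            raise ValueError("global model must hold exactly one model per label")
        # normalise key order to label order
        self.models = {n: self.models[n] for n in names}

    @property
    def n_labels(self) -> int:
        return len(self.label_order)

    def predict_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-label predicted class values, one column per label in label
        order; for label j this equals M_j applied alone."""
        out = {}
        for lab in self.label_order:
            out[lab.name] = self.models[lab.name].predict_frame(X)
        return pd.DataFrame(out, index=X.index)

    def to_dict(self) -> dict:
        return {
            "format": "fmll-global-model",
            "label_order": [
                {"name": l.name, "classes": list(l.classes), "positive": l.positive}
                for l in self.label_order
            ],
            "models": {name: m.to_dict() for name, m in self.models.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GlobalModel":
        order = tuple(
            LabelSpec(l["name"], tuple(l["classes"]), l.get("positive"))
            for l in d["label_order"]
        )
        models = {name: REPTreeModel.from_dict(md) for name, md in d["models"].items()}
        return cls(models=models, label_order=order)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "GlobalModel":
        return cls.from_dict(json.loads(text))


def server_aggregate(
    models: Iterable[REPTreeModel], label_order: Sequence[LabelSpec]
) -> GlobalModel:
    """Aggregate received local models into G regardless of arrival order;
    duplicate or missing labels are errors."""
    by_label: dict[str, REPTreeModel] = {}
    for model in models:
        name = model.target.name
        if name in by_label:
            raise ValueError(f"duplicate model for label {name!r}")
        by_label[name] = model
    missing = [l.name for l in label_order if l.name not in by_label]
    if missing:
        raise ValueError(f"missing model(s) for label(s) {missing}")
    extra = set(by_label) - {l.name for l in label_order}
    if extra:
        raise ValueError(f"model(s) for undeclared label(s) {sorted(extra)}")
    return GlobalModel(models=by_label, label_order=tuple(label_order))


def predict_label_set(global_model: GlobalModel, row: Mapping) -> dict[str, str]:
    """Predicted label assignment Ŷ for one feature vector, in label order.

    For strict-binary clients the value is "1"/"0" (present/absent); the
    helper :func:`label_subset` turns this into the subset of present
    labels.  For per-label (multi-class) clients the value is the predicted
    class itself.
    """
    return {
        lab.name: global_model.models[lab.name].predict(row)
        for lab in global_model.label_order
    }


def label_subset(global_model: GlobalModel, row: Mapping) -> set[str]:
    """Ŷ as the set of labels whose client predicts presence (strict-binary
    clients only; the empty set is a legal prediction)."""
    out = set()
    for lab in global_model.label_order:
        model = global_model.models[lab.name]
        if model.mode != "strict_binary":
            raise ValueError("label subsets are defined for strict-binary clients")
        if model.predict(row) == "1":
            out.add(lab.name)
    return out


def train_global_model(
    dataset: MultiLabelDataset,
    config: REPTreeConfig | None = None,
    mode: str = "auto",
) -> GlobalModel:
    """End-to-end convenience: prepare clients, train each locally, and
    aggregate.  ``mode="auto"`` uses strict binary decomposition when every
    label is binary and per-label targets otherwise."""
    if mode == "auto":
        mode = "strict_binary" if all(l.is_binary for l in dataset.labels) else "per_label"
    clients = client_prepare(dataset, mode)
    trained = [client_train(c, config) for c in clients]
    return server_aggregate([c.local_model for c in trained], dataset.labels)
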