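"""Reduced-error pruning decision tree (REPTree) for categorical targets.

The tree is grown greedily by information-gain splitting — numeric features
split at the midpoint between consecutive distinct sorted values, nominal
features split multiway on all declared categories — and is then simplified
by reduced-error pruning: a seeded shuffle partitions the training rows into
``num_folds`` parts, fold 0 is held out, the remaining folds grow the tree,
and bottom-up any subtree whose hold-out misclassification count is not
beaten by a majority leaf is collapsed to that leaf (ties prune, preferring
the smaller tree).

Missing feature values are routed to the heaviest child both while growing
and at prediction time (deterministic hard routing; no fractional instance
weighting).  Ordinal features are offered to the split search as numeric
rank values by default, or as nominal categories when
``REPTreeConfig.ordinal_as_nominal`` is set.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import FeatureSpec, LabelSpec, SingleTargetDataset

__all__ = [
    "REPTreeConfig",
    "TreeNode",
    "REPTreeModel",
    "entropy",
    "best_split",
    "grow_tree",
    "reduced_error_prune",
    "fit_reptree",
    "render_tree",
    "IGNORED_CONFIG_KEYS",
]

# Accepted in config documents for fidelity with the published hyperparameter
# surface but without effect on the learned model.
IGNORED_CONFIG_KEYS = ("batchSize", "debug", "doNotCheckCapabilities")


@dataclass(frozen=True)
class REPTreeConfig:
    """Hyperparameters of the learner.

    Defaults are the stock REPTree settings: unlimited depth, at least two
    instances per admissible child, three internal folds for the pruning
    hold-out, shuffle seed 1, no leaf-count smoothing.  ``min_variance_prop``
    and ``spread_initial_count`` are carried for config-surface fidelity but
    are inert here because every target is categorical.
    """

    max_depth: int = -1
    min_num: float = 2.0
    min_variance_prop: float = 0.001
    no_pruning: bool = False
    num_folds: int = 3
    seed: int = 1
    initial_count: float = 0.0
    spread_initial_count: bool = False
    num_decimal_places: int = 2
    ordinal_as_nominal: bool = False

    def __post_init__(self) -> None:
        if self.min_num <= 0:
            raise ValueError("min_num must be positive")
        if not self.no_pruning and self.num_folds < 2:
            raise ValueError("num_folds must be >= 2 when pruning is enabled")


class TreeNode:
    """One node: a leaf, or a split plus ordered children.

    ``class_counts`` are the training instances routed here;
    ``prune_counts`` the hold-out instances (all zeros when pruning is off).
    """

    __slots__ = (
        "class_counts",
        "prune_counts",
        "depth",
        "feature_index",
        "feature_name",
        "kind",
        "threshold",
        "categories",
        "children",
    )

    def __init__(self, class_counts: np.ndarray, depth: int) -> None:
        self.class_counts = np.asarray(class_counts, dtype=float)
        self.prune_counts = np.zeros_like(self.class_counts)
        self.depth = depth
        self.feature_index: int | None = None
        self.feature_name: str | None = None
        self.kind: str | None = None
        self.threshold: float | None = None
        self.categories: tuple[str, ...] | None = None
        self.children: list[TreeNode] = []

    @property
    def is_leaf(self) -> bool:
        return self.feature_index is None

    @property
    def predicted_class(self) -> int:
        # np.argmax breaks ties by class declaration order
        return int(np.argmax(self.class_counts))

    def make_leaf(self) -> None:
        self.feature_index = None
        self.feature_name = None
        self.kind = None
        self.threshold = None
        self.categories = None
        self.children = []

    def node_count(self) -> int:
        return 1 + sum(c.node_count() for c in self.children)


@dataclass(frozen=True)
class CandidateSplit:
    feature_index: int
    kind: str  # "numeric" | "nominal"
    gain: float
    threshold: float | None = None


# ---------------------------------------------------------------------------
# Entropy and split search
# ---------------------------------------------------------------------------


def entropy(class_counts) -> float:
    """Shannon entropy in bits of a class-count vector; 0 for pure nodes."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative class counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy of an empty count vector is undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Row-wise entropy of a (m, C) count matrix (0 rows give 0)."""
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), 0.0)
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logp).sum(axis=1)


def _numeric_split(
    x: np.ndarray, y: np.ndarray, n_classes: int, min_num: float
) -> tuple[float, float] | None:
    """Best midpoint threshold for one numeric column.

    Returns (threshold, gain) over the non-missing rows, with the gain
    scaled by the fraction of rows that are non-missing; None when no
    admissible threshold exists or no gain is positive.
    """
    present = ~np.isnan(x)
    xs = x[present]
    if xs.size < 2:
        return None
    order = np.argsort(xs, kind="stable")
    xs = xs[order]
    ys = y[present][order]
    boundaries = np.nonzero(xs[1:] != xs[:-1])[0]
    if boundaries.size == 0:
        return None
    onehot = np.zeros((xs.size, n_classes))
    onehot[np.arange(xs.size), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)
    left = cum[boundaries]
    total = cum[-1]
    right = total - left
    nl = left.sum(axis=1)
    nr = right.sum(axis=1)
    admissible = (nl >= min_num) & (nr >= min_num)
    if not admissible.any():
        return None
    n = xs.size
    parent_h = entropy(total)
    gains = parent_h - (nl * _entropy_rows(left) + nr * _entropy_rows(right)) / n
    gains = np.where(admissible, gains, -np.inf)
    best = int(np.argmax(gains))  # first max = smallest threshold
    if gains[best] <= 0:
        return None
    thr = float((xs[boundaries[best]] + xs[boundaries[best] + 1]) / 2.0)
    frac_present = xs.size / x.size
    return thr, float(gains[best]) * frac_present


def _nominal_split(
    x: np.ndarray, y: np.ndarray, n_categories: int, n_classes: int, min_num: float
) -> float | None:
    """Gain of the multiway split on all declared categories, or None when
    any category branch would carry fewer than ``min_num`` instances."""
    present = ~np.isnan(x)
    xs = x[present].astype(np.int64)
    if xs.size < 2:
        return None
    counts = np.zeros((n_categories, n_classes))
    np.add.at(counts, (xs, y[present]), 1.0)
    branch_n = counts.sum(axis=1)
    if np.any(branch_n < min_num):
        return None
    n = xs.size
    parent_h = entropy(counts.sum(axis=0))
    gain = parent_h - float((branch_n * _entropy_rows(counts)).sum()) / n
    if gain <= 0:
        return None
    frac_present = xs.size / x.size
    return gain * frac_present


def best_split(
    x,
    y,
    *,
    kind: str = "numeric",
    n_categories: int | None = None,
    n_classes: int | None = None,
    min_num: float = 2.0,
) -> CandidateSplit | None:
    """Best admissible split of one feature column.

    ``x`` holds floats (NaN = missing) for numeric features or non-negative
    integer category codes (NaN = missing) for nominal ones; ``y`` holds
    integer class codes.  Returns None when no admissible split has
    positive information gain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if n_classes is None:
        n_classes = int(y.max()) + 1 if y.size else 1
    if kind == "numeric":
        res = _numeric_split(x, y, n_classes, min_num)
        if res is None:
            return None
        thr, gain = res
        return CandidateSplit(0, "numeric", gain, thr)
    if kind == "nominal":
        if n_categories is None:
            present = ~np.isnan(x)
            n_categories = int(x[present].max()) + 1 if present.any() else 0
        gain = _nominal_split(x, y, n_categories, n_classes, min_num)
        if gain is None:
            return None
        return CandidateSplit(0, "nominal", gain)
    raise ValueError(f"unknown feature kind {kind!r}")


# ---------------------------------------------------------------------------
# Encoded data
# ---------------------------------------------------------------------------


@dataclass
class EncodedData:
    """Column-encoded training data: every column a float array with NaN as
    the missing marker (nominal columns hold category codes)."""

    cols: list[np.ndarray]
    kinds: list[str]  # per column: "numeric" | "nominal"
    n_categories: list[int]
    names: list[str]
    category_maps: list[tuple[str, ...] | None]
    y: np.ndarray
    n_classes: int


def _encode_column(values: pd.Series, spec: FeatureSpec, config: REPTreeConfig):
    if spec.kind == "numeric":
        return values.to_numpy(dtype=float), "numeric", 0, None
    rank = {c: float(i) for i, c in enumerate(spec.categories)}
    arr = np.array(
        [np.nan if v is None or (isinstance(v, float) and np.isnan(v)) else rank[v]
         for v in values],
        dtype=float,
    )
    if spec.kind == "ordinal" and not config.ordinal_as_nominal:
        return arr, "numeric", 0, spec.categories
    return arr, "nominal", len(spec.categories), spec.categories


def encode_dataset(data: SingleTargetDataset, config: REPTreeConfig) -> EncodedData:
    cols, kinds, ncats, names, cmaps = [], [], [], [], []
    for spec in data.features:
        arr, kind, ncat, cmap = _encode_column(data.X[spec.name], spec, config)
        cols.append(arr)
        kinds.append(kind)
        ncats.append(ncat)
        names.append(spec.name)
        cmaps.append(cmap)
    y = data.target_codes()
    return EncodedData(cols, kinds, ncats, names, cmaps, y, len(data.target_classes))


# ---------------------------------------------------------------------------
# Growing
# ---------------------------------------------------------------------------


def _partition(enc: EncodedData, idx: np.ndarray, node: TreeNode) -> list[np.ndarray]:
    """Split the index set by the node's test; missing values join the
    heaviest child (first heaviest on ties)."""
    x = enc.cols[node.feature_index][idx]
    missing = np.isnan(x)
    if node.kind == "numeric":
        groups = [idx[(~missing) & (x < node.threshold)], idx[(~missing) & (x >= node.threshold)]]
    else:
        groups = [idx[(~missing) & (x == c)] for c in range(len(node.categories))]
    if missing.any():
        sizes = [g.size for g in groups]
        heaviest = int(np.argmax(sizes))
        groups[heaviest] = np.concatenate([groups[heaviest], idx[missing]])
    return groups


def grow_tree(enc: EncodedData, idx: np.ndarray, config: REPTreeConfig, depth: int = 0) -> TreeNode:
    """Recursively grow an unpruned tree over the given row indices."""
    counts = np.bincount(enc.y[idx], minlength=enc.n_classes).astype(float)
    node = TreeNode(counts, depth)
    total = idx.size
    if (
        counts.max() == total  # pure
        or (config.max_depth >= 0 and depth >= config.max_depth)
        or total < 2 * config.min_num
    ):
        return node
    best: CandidateSplit | None = None
    for f in range(len(enc.cols)):
        cand = best_split(
            enc.cols[f][idx],
            enc.y[idx],
            kind=enc.kinds[f],
            n_categories=enc.n_categories[f] or None,
            n_classes=enc.n_classes,
            min_num=config.min_num,
        )
        if cand is not None and (best is None or cand.gain > best.gain):
            best = CandidateSplit(f, cand.kind, cand.gain, cand.threshold)
    if best is None:
        return node
    node.feature_index = best.feature_index
    node.feature_name = enc.names[best.feature_index]
    node.kind = best.kind
    node.threshold = best.threshold
    if best.kind == "nominal":
        node.categories = enc.category_maps[best.feature_index]
    node.children = [
        grow_tree(enc, child_idx, config, depth + 1)
        for child_idx in _partition(enc, idx, node)
    ]
    return node


# ---------------------------------------------------------------------------
# Reduced-error pruning
# ---------------------------------------------------------------------------


def _route_prune(enc: EncodedData, node: TreeNode, idx: np.ndarray) -> None:
    node.prune_counts = np.bincount(enc.y[idx], minlength=enc.n_classes).astype(float)
    if node.is_leaf:
        return
    x = enc.cols[node.feature_index][idx]
    missing = np.isnan(x)
    if node.kind == "numeric":
        groups = [idx[(~missing) & (x < node.threshold)], idx[(~missing) & (x >= node.threshold)]]
    else:
        groups = [idx[(~missing) & (x == c)] for c in range(len(node.categories))]
    if missing.any():
        weights = [c.class_counts.sum() for c in node.children]
        heaviest = int(np.argmax(weights))
        groups[heaviest] = np.concatenate([groups[heaviest], idx[missing]])
    for child, g in zip(node.children, groups):
        _route_prune(enc, child, g)


def _prune_bottom_up(node: TreeNode) -> float:
    """Collapse subtrees whose hold-out error is matched by a majority leaf;
    returns the subtree's hold-out misclassification count after pruning."""
    total = node.prune_counts.sum()
    leaf_err = total - node.prune_counts[node.predicted_class]
    if node.is_leaf:
        return leaf_err
    subtree_err = sum(_prune_bottom_up(child) for child in node.children)
    if leaf_err <= subtree_err:  # ties prune: prefer the smaller tree
        node.make_leaf()
        return leaf_err
    return subtree_err


def reduced_error_prune(root: TreeNode, enc: EncodedData, prune_idx: np.ndarray) -> TreeNode:
    """Route the hold-out rows, record per-node hold-out counts, and prune
    bottom-up.  Mutates and returns ``root``."""
    _route_prune(enc, root, np.asarray(prune_idx, dtype=np.int64))
    _prune_bottom_up(root)
    return root


# ---------------------------------------------------------------------------
# Fitted model
# ---------------------------------------------------------------------------


@dataclass
class REPTreeModel:
    """A grown-and-pruned tree bound to its target and feature schema."""

    root: TreeNode
    config: REPTreeConfig
    target: LabelSpec
    target_classes: tuple[str, ...]
    feature_schema: tuple[FeatureSpec, ...]
    mode: str = "strict_binary"

    # -- prediction -----------------------------------------------------
    def _encode_frame(self, X: pd.DataFrame) -> list[np.ndarray]:
        cols = []
        for spec in self.feature_schema:
            if spec.name not in X.columns:
                raise ValueError(f"query data lacks feature {spec.name!r}")
            arr, _, _, _ = _encode_column(X[spec.name], spec, self.config)
            cols.append(arr)
        return cols

    def _leaf_assignment(self, cols: list[np.ndarray], n: int) -> tuple[list[TreeNode], np.ndarray]:
        """Route every row to a leaf; returns (leaves, per-row leaf index)."""
        leaves: list[TreeNode] = []
        assign = np.empty(n, dtype=np.int64)

        def walk(node: TreeNode, idx: np.ndarray) -> None:
            if node.is_leaf:
                leaves.append(node)
                assign[idx] = len(leaves) - 1
                return
            x = cols[node.feature_index][idx]
            missing = np.isnan(x)
            if node.kind == "numeric":
                groups = [
                    idx[(~missing) & (x < node.threshold)],
                    idx[(~missing) & (x >= node.threshold)],
                ]
            else:
                groups = [idx[(~missing) & (x == c)] for c in range(len(node.categories))]
            if missing.any():
                weights = [c.class_counts.sum() for c in node.children]
                heaviest = int(np.argmax(weights))
                groups[heaviest] = np.concatenate([groups[heaviest], idx[missing]])
            for child, g in zip(node.children, groups):
                if g.size:
                    walk(child, g)

        walk(self.root, np.arange(n, dtype=np.int64))
        return leaves, assign

    def _leaf_distributions(self) -> dict[int, np.ndarray]:
        """Effective smoothed distribution per leaf (empty leaves inherit
        the nearest ancestor with training instances)."""
        out: dict[int, np.ndarray] = {}
        ic = self.config.initial_count

        def walk(node: TreeNode, inherited: np.ndarray) -> None:
            counts = node.class_counts
            effective = counts if counts.sum() > 0 else inherited
            if node.is_leaf:
                smoothed = effective + ic
                total = smoothed.sum()
                if total <= 0:  # all-zero counts and no smoothing: uniform
                    smoothed = np.ones_like(smoothed)
                    total = smoothed.sum()
                out[id(node)] = smoothed / total
                return
            for child in node.children:
                walk(child, effective)

        walk(self.root, self.root.class_counts)
        return out

    def predict_frame(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted class value (string) per row."""
        cols = self._encode_frame(X)
        leaves, assign = self._leaf_assignment(cols, len(X))
        preds = np.array([leaf.predicted_class for leaf in leaves], dtype=np.int64)
        classes = np.array(self.target_classes, dtype=object)
        return classes[preds[assign]]

    def predict_proba_frame(self, X: pd.DataFrame) -> np.ndarray:
        """(n, C) class-probability matrix in ``target_classes`` order."""
        cols = self._encode_frame(X)
        leaves, assign = self._leaf_assignment(cols, len(X))
        dists = self._leaf_distributions()
        mat = np.stack([dists[id(leaf)] for leaf in leaves])
        return mat[assign]

    def predict(self, row: Mapping) -> str:
        frame = pd.DataFrame({k: [v] for k, v in dict(row).items()})
        for spec in self.feature_schema:
            if spec.name not in frame.columns:
                frame[spec.name] = [None]
        return str(self.predict_frame(frame)[0])

    def predict_distribution(self, row: Mapping) -> np.ndarray:
        frame = pd.DataFrame({k: [v] for k, v in dict(row).items()})
        for spec in self.feature_schema:
            if spec.name not in frame.columns:
                frame[spec.name] = [None]
        return self.predict_proba_frame(frame)[0]

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        def node_dict(node: TreeNode) -> dict:
            d: dict = {
                "class_counts": node.class_counts.tolist(),
                "prune_counts": node.prune_counts.tolist(),
                "depth": node.depth,
            }
            if not node.is_leaf:
                d["split"] = {
                    "feature": node.feature_name,
                    "feature_index": node.feature_index,
                    "kind": node.kind,
                    "threshold": node.threshold,
                    "categories": list(node.categories) if node.categories else None,
                }
                d["children"] = [node_dict(c) for c in node.children]
            return d

        return {
            "format": "fmll-reptree",
            "target": {
                "name": self.target.name,
                "classes": list(self.target.classes),
                "positive": self.target.positive,
            },
            "target_classes": list(self.target_classes),
            "mode": self.mode,
            "config": asdict(self.config),
            "features": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    "categories": list(f.categories),
                    "role": f.role,
                }
                for f in self.feature_schema
            ],
            "root": node_dict(self.root),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "REPTreeModel":
        config = REPTreeConfig(**d["config"])

        def build(nd: Mapping, depth: int) -> TreeNode:
            node = TreeNode(np.array(nd["class_counts"], dtype=float), nd.get("depth", depth))
            node.prune_counts = np.array(nd["prune_counts"], dtype=float)
            if "split" in nd:
                s = nd["split"]
                node.feature_index = s["feature_index"]
                node.feature_name = s["feature"]
                node.kind = s["kind"]
                node.threshold = s["threshold"]
                node.categories = tuple(s["categories"]) if s["categories"] else None
                node.children = [build(c, depth + 1) for c in nd["children"]]
            return node

        t = d["target"]
        target = LabelSpec(t["name"], tuple(t["classes"]), t.get("positive"))
        features = tuple(
            FeatureSpec(f["name"], f["kind"], tuple(f["categories"]), f["role"])
            for f in d["features"]
        )
        return cls(
            root=build(d["root"], 0),
            config=config,
            target=target,
            target_classes=tuple(d["target_classes"]),
            feature_schema=features,
            mode=d.get("mode", "strict_binary"),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "REPTreeModel":
        return cls.from_dict(json.loads(text))


def fit_reptree(data: SingleTargetDataset, config: REPTreeConfig | None = None) -> REPTreeModel:
    """Train a REPTree on one client's single-target dataset.

    With pruning on, a shuffle seeded by ``config.seed`` partitions the rows
    into ``num_folds`` parts; fold 0 is the pruning hold-out and the
    remainder grows the tree, after which reduced-error pruning runs and the
    hold-out class counts stay recorded on every surviving node.
    """
    config = config or REPTreeConfig()
    n = data.n_samples
    if n < 1:
        raise ValueError("cannot fit on an empty dataset")
    enc = encode_dataset(data, config)
    if config.no_pruning:
        root = grow_tree(enc, np.arange(n, dtype=np.int64), config)
    else:
        if n < config.num_folds:
            raise ValueError(
                f"pruning needs at least num_folds={config.num_folds} rows, got {n}"
            )
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(n)
        prune_size = n // config.num_folds + (1 if n % config.num_folds else 0)
        prune_idx = np.sort(perm[:prune_size])
        grow_idx = np.sort(perm[prune_size:])
        root = grow_tree(enc, grow_idx, config)
        reduced_error_prune(root, enc, prune_idx)
    return REPTreeModel(
        root=root,
        config=config,
        target=data.source_label,
        target_classes=data.target_classes,
        feature_schema=data.features,
        mode=data.mode,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _fmt_count(x: float, dp: int) -> str:
    if float(x).is_integer():
        return str(int(x))
    return f"{x:.{dp}f}"


def _leaf_text(node: TreeNode, classes: Sequence[str], dp: int, bracket: str) -> str:
    train_total = node.class_counts.sum()
    train_err = train_total - node.class_counts[node.predicted_class]
    prune_total = node.prune_counts.sum()
    if bracket == "majority":
        c = node.prune_counts.max() if prune_total > 0 else 0.0
        d = prune_total - c
    elif bracket == "holdout_error":
        c = prune_total
        d = prune_total - (node.prune_counts[node.predicted_class] if prune_total else 0.0)
    else:
        raise ValueError(f"unknown bracket style {bracket!r}")
    return (
        f"{classes[node.predicted_class]} "
        f"({_fmt_count(train_total, dp)}/{_fmt_count(train_err, dp)}) "
        f"[{_fmt_count(c, dp)}/{_fmt_count(d, dp)}]"
    )


def render_tree(model: REPTreeModel, bracket: str = "majority") -> str:
    """Indented text rendering of the tree.

    Leaves print ``CLASS (a/b) [c/d]`` with a = training instances reaching
    the leaf and b = training misclassifications.  The hold-out bracket
    defaults to ``majority`` semantics (c = hold-out instances of the leaf's
    majority class, d = the rest); ``bracket="holdout_error"`` switches to
    the total/misclassified convention.
    """
    dp = model.config.num_decimal_places
    classes = model.target_classes
    lines: list[str] = []

    def branch_label(node: TreeNode, i: int) -> str:
        if node.kind == "numeric":
            op = "<" if i == 0 else ">="
            return f"{node.feature_name} {op} {node.threshold:.{dp}f}"
        return f"{node.feature_name} = {node.categories[i]}"

    def walk(node: TreeNode, prefix: str) -> None:
        for i, child in enumerate(node.children):
            label = prefix + branch_label(node, i)
            if child.is_leaf:
                lines.append(f"{label} : {_leaf_text(child, classes, dp, bracket)}")
            else:
                lines.append(label)
                walk(child, prefix + "|   ")

    if model.root.is_leaf:
        return _leaf_text(model.root, classes, dp, bracket)
    walk(model.root, "")
    return "\n".join(lines)
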