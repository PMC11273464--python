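"""Synthetic multi-label data with planted, tree-recoverable label rules.

Features are drawn independently (numeric uniform over a range, nominal
uniform over categories).  Each label's noiseless value is assigned by a
planted axis-aligned decision rule — single-feature numeric threshold tests
and nominal category-membership tests, so the truth lies inside the REPTree
hypothesis class — then replaced uniformly at random over the label's class
inventory with probability ``label_noise`` (a uniform replacement hits the
true class with probability 1/c, so the observed disagreement rate is
``label_noise·(c−1)/c``).  A missing mask is applied to input features
after labelling.  Everything is driven by numpy's seeded PCG64 generator,
so a config and seed reproduce the dataset bit for bit.

Presets emulate the column structure of the three public study datasets
(an amphibian habitat survey, an anuran-call MFCC table, and a pet-adoption
registry); they match shapes and schemas only, not marginal statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import FeatureSpec, LabelSpec, MultiLabelDataset

__all__ = ["NumericFeature", "NominalFeature", "LabelDef", "SynthConfig",
           "PlantedRule", "generate", "preset"]


@dataclass(frozen=True)
class NumericFeature:
    name: str
    low: float
    high: float
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"feature {self.name!r} needs low < high")


@dataclass(frozen=True)
class NominalFeature:
    name: str
    n_categories: int
    ordinal: bool = False

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError(f"feature {self.name!r} needs >= 2 categories")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(str(i) for i in range(1, self.n_categories + 1))


@dataclass(frozen=True)
class LabelDef:
    name: str
    n_classes: int

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"label {self.name!r} needs >= 2 classes")

    @property
    def classes(self) -> tuple[str, ...]:
        if self.n_classes == 2:
            return ("0", "1")
        return tuple(str(i) for i in range(self.n_classes))


@dataclass(frozen=True)
class SynthConfig:
    name: str
    n_samples: int
    numeric_features: tuple[NumericFeature, ...]
    nominal_features: tuple[NominalFeature, ...]
    labels: tuple[LabelDef, ...]
    rule_depth: int = 3
    label_noise: float = 0.0
    missing_rate: float = 0.0
    seed: int = 1
    with_identifier: bool = False  # emit an ID metadata column

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.numeric_features and not self.nominal_features:
            raise ValueError("need at least one input feature")
        if not self.labels:
            raise ValueError("need at least one label")
        if self.rule_depth < 1:
            raise ValueError("rule_depth must be >= 1")
        for p, nm in ((self.label_noise, "label_noise"), (self.missing_rate, "missing_rate")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Planted rules
# ---------------------------------------------------------------------------


@dataclass
class PlantedRule:
    """Noiseless generating rule for one label: a nested dict tree.

    Internal nodes: ``{"feature": name, "kind": "numeric", "threshold": t,
    "low": subtree, "high": subtree}`` or ``{"kind": "nominal",
    "in_categories": [...], "inside": subtree, "outside": subtree}``;
    leaves: ``{"class": value}``.
    """

    label: str
    tree: dict

    def apply_frame(self, X: pd.DataFrame) -> np.ndarray:
        """Vectorised noiseless label values for a full feature block
        (missing-free inputs; the mask is applied after labelling)."""
        n = len(X)
        out = np.empty(n, dtype=object)

        def walk(node: Mapping, idx: np.ndarray) -> None:
            if "class" in node:
                out[idx] = node["class"]
                return
            col = X[node["feature"]].to_numpy()
            if node["kind"] == "numeric":
                go = col[idx].astype(float) < node["threshold"]
                walk(node["low"], idx[go])
                walk(node["high"], idx[~go])
            else:
                members = np.isin(col[idx].astype(object), list(node["in_categories"]))
                walk(node["inside"], idx[members])
                walk(node["outside"], idx[~members])

        walk(self.tree, np.arange(n, dtype=np.int64))
        return out

    def depth(self) -> int:
        def d(node: Mapping) -> int:
            if "class" in node:
                return 0
            kids = (node["low"], node["high"]) if node["kind"] == "numeric" else (
                node["inside"], node["outside"])
            return 1 + max(d(k) for k in kids)

        return d(self.tree)

    def to_dict(self) -> dict:
        return {"label": self.label, "tree": self.tree}


def _build_rule(
    rng: np.random.Generator,
    numeric: Sequence[NumericFeature],
    nominal: Sequence[NominalFeature],
    depth: int,
    used: frozenset = frozenset(),
) -> dict:
    """Random axis-aligned rule of exactly ``depth`` levels (leaves carry a
    placeholder class index filled in afterwards).

    A feature is tested at most once per root-to-leaf path; ordinal
    features get contiguous prefix cuts (equivalent to one rank threshold)
    so the rule stays expressible with single learner splits.
    """
    if depth == 0:
        return {"class": None}
    feats: list = [f for f in list(numeric) + list(nominal) if f.name not in used]
    if not feats:
        return {"class": None}
    f = feats[int(rng.integers(len(feats)))]
    sub = used | {f.name}
    if isinstance(f, NumericFeature):
        # central thresholds keep both branches well populated
        lo = f.low + 0.3 * (f.high - f.low)
        hi = f.low + 0.7 * (f.high - f.low)
        thr = float(rng.uniform(lo, hi))
        if f.integer:
            thr = float(np.floor(thr)) + 0.5
        return {
            "feature": f.name,
            "kind": "numeric",
            "threshold": thr,
            "low": _build_rule(rng, numeric, nominal, depth - 1, sub),
            "high": _build_rule(rng, numeric, nominal, depth - 1, sub),
        }
    cats = list(f.categories)
    if f.ordinal:
        cut = int(rng.integers(1, len(cats)))
        members = cats[:cut]
    else:
        size = int(rng.integers(1, len(cats)))
        members = sorted(rng.choice(cats, size=size, replace=False).tolist())
    return {
        "feature": f.name,
        "kind": "nominal",
        "in_categories": members,
        "inside": _build_rule(rng, numeric, nominal, depth - 1, sub),
        "outside": _build_rule(rng, numeric, nominal, depth - 1, sub),
    }


def _assign_leaf_classes(tree: dict, classes: Sequence[str], rng: np.random.Generator) -> None:
    """Fill leaf placeholders with a shuffled cyclic draw from the class
    inventory, so a depth-d rule realises min(2**d, len(classes)) distinct
    classes in a random arrangement."""
    leaves: list[dict] = []

    def collect(node: dict) -> None:
        if "class" in node:
            leaves.append(node)
            return
        kids = ("low", "high") if node["kind"] == "numeric" else ("inside", "outside")
        for k in kids:
            collect(node[k])

    collect(tree)
    pool = [classes[i % len(classes)] for i in range(len(leaves))]
    order = rng.permutation(len(pool))
    for leaf, j in zip(leaves, order):
        leaf["class"] = pool[j]


def _prob_entropy(p: np.ndarray) -> float:
    q = p[p > 0]
    return float(-(q * np.log2(q)).sum()) if q.size else 0.0


def _rule_quality(
    tree: Mapping,
    classes: Sequence[str],
    numeric: Mapping[str, NumericFeature],
    nominal: Mapping[str, NominalFeature],
) -> float:
    """Minimum population information gain over the rule's internal tests.

    Branch probabilities follow the uniform feature marginals, so a greedy
    information-gain learner sees at least this much signal at every level
    of the planted tree; parity-like rules (zero gain at the top) score 0
    and are rejected by the generator.
    """
    index = {c: i for i, c in enumerate(classes)}

    def walk(node: Mapping) -> tuple[np.ndarray, float]:
        if "class" in node:
            vec = np.zeros(len(classes))
            vec[index[node["class"]]] = 1.0
            return vec, float("inf")
        if node["kind"] == "numeric":
            f = numeric[node["feature"]]
            p = (node["threshold"] - f.low) / (f.high - f.low)
            kids = (node["low"], node["high"])
        else:
            f = nominal[node["feature"]]
            p = len(node["in_categories"]) / f.n_categories
            kids = (node["inside"], node["outside"])
        p = min(max(p, 1e-6), 1 - 1e-6)
        d_in, g_in = walk(kids[0])
        d_out, g_out = walk(kids[1])
        mix = p * d_in + (1 - p) * d_out
        gain = _prob_entropy(mix) - p * _prob_entropy(d_in) - (1 - p) * _prob_entropy(d_out)
        return mix, min(gain, g_in, g_out)

    _, min_gain = walk(tree)
    return min_gain


def _canonicalize(node: dict) -> set:
    """Collapse subtrees whose leaves all share one class into a leaf;
    returns the set of classes reachable under ``node``."""
    if "class" in node:
        return {node["class"]}
    kids = ("low", "high") if node["kind"] == "numeric" else ("inside", "outside")
    seen = set()
    for k in kids:
        seen |= _canonicalize(node[k])
    if len(seen) == 1:
        cls = next(iter(seen))
        node.clear()
        node["class"] = cls
    return seen


_MIN_RULE_GAIN = 0.12  # bits of signal required at every internal test
_MAX_RULE_DRAWS = 500


def _plant_rule(
    rng: np.random.Generator,
    config: SynthConfig,
    label: LabelDef,
) -> PlantedRule:
    """Draw candidate rules until every internal test carries at least
    ``_MIN_RULE_GAIN`` bits of population information gain (keeping the
    best candidate if the margin is never reached)."""
    num_map = {f.name: f for f in config.numeric_features}
    nom_map = {f.name: f for f in config.nominal_features}
    best_tree, best_gain = None, -1.0
    for _ in range(_MAX_RULE_DRAWS):
        tree = _build_rule(rng, config.numeric_features, config.nominal_features,
                           config.rule_depth)
        _assign_leaf_classes(tree, label.classes, rng)
        if len(_canonicalize(tree)) < 2:
            continue  # degenerate constant rule
        gain = _rule_quality(tree, label.classes, num_map, nom_map)
        if gain > best_gain:
            best_tree, best_gain = tree, gain
        if gain >= _MIN_RULE_GAIN:
            break
    return PlantedRule(label.name, best_tree)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(config: SynthConfig) -> tuple[MultiLabelDataset, list[PlantedRule]]:
    """Draw a dataset and its per-label planted rules, fully determined by
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    xcols: dict[str, pd.Series] = {}
    feats: list[FeatureSpec] = []
    for f in config.numeric_features:
        vals = rng.uniform(f.low, f.high, size=n)
        if f.integer:
            vals = np.floor(vals)
        xcols[f.name] = pd.Series(vals.astype(float))
        feats.append(FeatureSpec(f.name, "numeric"))
    for f in config.nominal_features:
        codes = rng.integers(0, f.n_categories, size=n)
        cats = f.categories
        xcols[f.name] = pd.Series([cats[c] for c in codes], dtype=object)
        feats.append(FeatureSpec(f.name, "ordinal" if f.ordinal else "nominal", cats))

    X = pd.DataFrame({f.name: xcols[f.name] for f in feats})

    rules: list[PlantedRule] = []
    ycols: dict[str, np.ndarray] = {}
    labels: list[LabelSpec] = []
    for lab in config.labels:
        rule = _plant_rule(rng, config, lab)
        values = rule.apply_frame(X)
        if config.label_noise > 0:
            flip = rng.random(n) < config.label_noise
            repl = rng.integers(0, lab.n_classes, size=n)
            values = values.copy()
            values[flip] = np.array(lab.classes, dtype=object)[repl[flip]]
        positive = "1" if lab.n_classes == 2 else None
        labels.append(LabelSpec(lab.name, lab.classes, positive))
        ycols[lab.name] = values
        rules.append(rule)

    if config.missing_rate > 0:
        mask = rng.random((n, len(feats))) < config.missing_rate
        for j, spec in enumerate(feats):
            col = X[spec.name]
            if spec.kind == "numeric":
                X[spec.name] = col.mask(mask[:, j], other=np.nan)
            else:
                X[spec.name] = col.mask(mask[:, j], other=None)

    Y = pd.DataFrame(ycols)[[l.name for l in labels]]
    extras = None
    if config.with_identifier:
        extras = pd.DataFrame({"ID": np.arange(1, n + 1)})
    dataset = MultiLabelDataset(config.name, tuple(feats), tuple(labels), X, Y, extras)
    return dataset, rules


# ---------------------------------------------------------------------------
# Presets emulating the three study datasets
# ---------------------------------------------------------------------------


def preset(shape: str, **overrides) -> SynthConfig:
    """Config matching a study dataset's column structure.

    ``amphibians``: 189 samples, 3 numeric + 2 ordinal + 9 nominal inputs,
    7 binary labels (habitat-survey layout).  ``anuran``: 7195 samples,
    22 numeric MFCC-style inputs, 3 multi-class labels with 4/8/10 classes.
    ``adopt_a_buddy``: 18 834 samples, mixed inputs, labels with 3/4
    classes.  Keyword overrides replace any config field (e.g.
    ``n_samples``, ``label_noise``, ``seed``).
    """
    if shape == "amphibians":
        cfg = SynthConfig(
            name="synthetic-amphibians",
            n_samples=189,
            numeric_features=(
                NumericFeature("SR", 30, 500000, integer=True),
                NumericFeature("NR", 1, 12, integer=True),
                NumericFeature("OR", 25, 100, integer=True),
            ),
            nominal_features=(
                NominalFeature("TR", 5),
                NominalFeature("VR", 5),
                NominalFeature("SUR1", 6),
                NominalFeature("SUR2", 6),
                NominalFeature("SUR3", 6),
                NominalFeature("UR", 4),
                NominalFeature("FR", 4),
                NominalFeature("RR", 6, ordinal=True),
                NominalFeature("BR", 6, ordinal=True),
                NominalFeature("MR", 3),
                NominalFeature("CR", 2),
            ),
            labels=tuple(
                LabelDef(nm, 2)
                for nm in (
                    "Green frogs", "Brown frogs", "Common toad", "Fire-bellied toad",
                    "Tree frog", "Common newt", "Great crested newt",
                )
            ),
            with_identifier=True,
        )
    elif shape == "anuran":
        cfg = SynthConfig(
            name="synthetic-anuran",
            n_samples=7195,
            numeric_features=tuple(
                NumericFeature(f"MFCCs_{i}", -1.0, 1.0) for i in range(1, 23)
            ),
            nominal_features=(),
            labels=(LabelDef("Family", 4), LabelDef("Genus", 8), LabelDef("Species", 10)),
        )
    elif shape == "adopt_a_buddy":
        cfg = SynthConfig(
            name="synthetic-adopt-a-buddy",
            n_samples=18834,
            numeric_features=(
                NumericFeature("length", 0.0, 1.0),
                NumericFeature("height", 5.0, 50.0),
                NumericFeature("X1", 0, 19, integer=True),
                NumericFeature("X2", 0, 9, integer=True),
            ),
            nominal_features=(
                NominalFeature("condition", 3),
                NominalFeature("color_type", 10),
            ),
            labels=(LabelDef("breed_category", 3), LabelDef("pet_category", 4)),
            with_identifier=True,
        )
    else:
        raise ValueError(f"unknown preset shape {shape!r}")
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def write_rules(rules: Sequence[PlantedRule], path) -> None:
    """Rule-oracle sidecar document for a generated dataset."""
    with open(path, "w") as fh:
        json.dump({"format": "fmll-planted-rules",
                   "rules": [r.to_dict() for r in rules]}, fh, indent=2)


def read_rules(path) -> list[PlantedRule]:
    with open(path) as fh:
        d = json.load(fh)
    return [PlantedRule(r["label"], r["tree"]) for r in d["rules"]]
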