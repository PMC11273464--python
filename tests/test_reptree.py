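"""The REPTree learner: entropy, split search, growing, pruning,
prediction, rendering, serialization, and the brute-force split oracle."""

import copy
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fmll.reptree import (
    EncodedData,
    REPTreeConfig,
    REPTreeModel,
    TreeNode,
    best_split,
    entropy,
    fit_reptree,
    grow_tree,
    reduced_error_prune,
    render_tree,
)
from fmll.datasets import FeatureSpec, LabelSpec

from conftest import single_target


# ---------------------------------------------------------------------------
# Brute-force split oracle: exhaustive enumeration of every admissible
# numeric threshold and the full multiway nominal partition.
# ---------------------------------------------------------------------------


def oracle_best_gain(cols, kinds, n_cats, y, n_classes, min_num=1.0):
    """Max information gain over all features by exhaustive enumeration
    (missing-free data)."""

    def h(labels):
        if len(labels) == 0:
            return 0.0
        counts = np.bincount(labels, minlength=n_classes)
        p = counts[counts > 0] / len(labels)
        return float(-(p * np.log2(p)).sum())

    n = len(y)
    parent = h(y)
    best = None
    for f, (col, kind) in enumerate(zip(cols, kinds)):
        if kind == "numeric":
            vals = sorted(set(col))
            for lo, hi in zip(vals, vals[1:]):
                thr = (lo + hi) / 2.0
                left = y[col < thr]
                right = y[col >= thr]
                if len(left) < min_num or len(right) < min_num:
                    continue
                gain = parent - (len(left) * h(left) + len(right) * h(right)) / n
                if gain > 0 and (best is None or gain > best[0] + 1e-12):
                    best = (gain, f, thr)
        else:
            groups = [y[col == c] for c in range(n_cats[f])]
            if any(len(g) < min_num for g in groups):
                continue
            gain = parent - sum(len(g) * h(g) for g in groups) / n
            if gain > 0 and (best is None or gain > best[0] + 1e-12):
                best = (gain, f, None)
    return best


def learner_best(cols, kinds, n_cats, y, n_classes, min_num=1.0):
    best = None
    for f, (col, kind) in enumerate(zip(cols, kinds)):
        cand = best_split(
            np.asarray(col, dtype=float), y, kind=kind,
            n_categories=n_cats[f] or None, n_classes=n_classes, min_num=min_num,
        )
        if cand is not None and (best is None or cand.gain > best[0]):
            best = (cand.gain, f, cand.threshold)
    return best


class TestEntropy:
    @pytest.mark.parametrize(
        "counts, expected",
        [((4, 4), 1.0), ((8, 0), 0.0), ((9, 5), 0.9403), ((1, 1, 1, 1), 2.0)],
    )
    def test_values(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=5e-5)

    def test_empty_counts_error(self):
        with pytest.raises(ValueError):
            entropy((0, 0))


class TestBestSplit:
    def test_clean_numeric_threshold(self):
        """x=(1,2,3,4), classes (A,A,B,B): midpoint 2.5 with gain 1 bit."""
        cand = best_split([1, 2, 3, 4], [0, 0, 1, 1], min_num=2.0)
        assert cand.threshold == pytest.approx(2.5)
        assert cand.gain == pytest.approx(1.0)

    def test_min_num_filters_thresholds(self):
        # midpoints 1.5 and 3.5 leave a lone instance; only 2.5 is admissible
        cand = best_split([1, 2, 3, 4], [0, 1, 1, 0], min_num=2.0)
        assert cand is None or cand.threshold == pytest.approx(2.5)

    def test_single_distinct_value_absent(self):
        assert best_split([7, 7, 7], [0, 1, 0]) is None

    def test_nominal_two_branch_gain(self):
        """14 rows: branch counts (6,2) and (3,3) under parent (9,5) give
        gain ~= 0.048 (weighted child entropy 0.8922 vs parent 0.9403)."""
        x = [0] * 8 + [1] * 6
        y = [0] * 6 + [1] * 2 + [0] * 3 + [1] * 3
        cand = best_split(x, y, kind="nominal", n_categories=2, min_num=2.0)
        assert cand.gain == pytest.approx(0.048, abs=5e-4)

    def test_no_positive_gain_absent(self):
        assert best_split([1, 2, 3, 4], [0, 1, 0, 1], kind="numeric", min_num=1.0) is not None
        # a pure target cannot gain
        assert best_split([1, 2, 3, 4], [0, 0, 0, 0], min_num=1.0) is None

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_oracle(self, data):
        """On every dataset with <=6 rows and <=3 features, the chosen gain
        equals the exhaustive-enumeration maximum (and the chosen split when
        the maximiser is unique)."""
        n = data.draw(st.integers(2, 6))
        n_feats = data.draw(st.integers(1, 3))
        kinds, cols, n_cats = [], [], []
        for _ in range(n_feats):
            kind = data.draw(st.sampled_from(["numeric", "nominal"]))
            kinds.append(kind)
            if kind == "numeric":
                cols.append(np.array(data.draw(
                    st.lists(st.integers(0, 4), min_size=n, max_size=n)), dtype=float))
                n_cats.append(0)
            else:
                m = data.draw(st.integers(2, 3))
                cols.append(np.array(data.draw(
                    st.lists(st.integers(0, m - 1), min_size=n, max_size=n)), dtype=float))
                n_cats.append(m)
        y = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        expected = oracle_best_gain(cols, kinds, n_cats, y, 2)
        got = learner_best(cols, kinds, n_cats, y, 2)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert got[0] == pytest.approx(expected[0], abs=1e-9)


def encode_single(cols, kinds, n_cats, y, names=None):
    names = names or [f"f{i}" for i in range(len(cols))]
    cmaps = [None if k == "numeric" else tuple(str(c) for c in range(n_cats[i]))
             for i, k in enumerate(kinds)]
    return EncodedData(
        [np.asarray(c, dtype=float) for c in cols], list(kinds), list(n_cats),
        names, cmaps, np.asarray(y, dtype=np.int64), int(max(y)) + 1,
    )


class TestGrowTree:
    def test_pure_rows_single_leaf(self):
        enc = encode_single([[1, 2, 3]], ["numeric"], [0], [0, 0, 0])
        root = grow_tree(enc, np.arange(3), REPTreeConfig())
        assert root.is_leaf and root.predicted_class == 0

    def test_four_row_fixture_structure(self):
        enc = encode_single([[1, 2, 3, 4]], ["numeric"], [0], [0, 0, 1, 1])
        root = grow_tree(enc, np.arange(4), REPTreeConfig(min_num=2.0))
        assert not root.is_leaf and root.threshold == pytest.approx(2.5)
        assert all(c.is_leaf for c in root.children)
        assert [c.predicted_class for c in root.children] == [0, 1]
        assert max(c.depth for c in root.children) == 1

    def test_max_depth_zero_forces_leaf(self):
        enc = encode_single([[1, 2, 3, 4]], ["numeric"], [0], [0, 0, 1, 1])
        root = grow_tree(enc, np.arange(4), REPTreeConfig(max_depth=0))
        assert root.is_leaf

    @pytest.mark.parametrize("max_depth", [1, 2, 3])
    def test_depth_bound_respected(self, max_depth):
        rng = np.random.default_rng(0)
        enc = encode_single(
            [rng.integers(0, 6, 120), rng.integers(0, 3, 120)],
            ["numeric", "nominal"], [0, 3], rng.integers(0, 2, 120),
        )
        root = grow_tree(enc, np.arange(120), REPTreeConfig(max_depth=max_depth, min_num=1.0))

        def max_depth_of(node):
            return node.depth if node.is_leaf else max(max_depth_of(c) for c in node.children)

        assert max_depth_of(root) <= max_depth


def _tiny_prune_fixture():
    """Hand-built stump where the subtree makes 3 hold-out errors but a
    majority leaf would make only 2."""
    root = TreeNode(np.array([4.0, 2.0]), 0)  # predicts class 0
    root.feature_index = 0
    root.feature_name = "x"
    root.kind = "numeric"
    root.threshold = 0.5
    left = TreeNode(np.array([3.0, 1.0]), 1)  # predicts 0
    right = TreeNode(np.array([1.0, 1.0]), 1)  # tie -> predicts 0... make it 1
    right.class_counts = np.array([1.0, 2.0])
    root.children = [left, right]
    # hold-out: left gets (0,0,1) -> 1 error; right gets (0,0,1) -> 2 errors
    x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
    y = np.array([0, 0, 1, 0, 0, 1])
    enc = encode_single([x], ["numeric"], [0], y)
    return root, enc


class TestPruning:
    def test_collapses_when_leaf_no_worse(self):
        root, enc = _tiny_prune_fixture()
        pruned = reduced_error_prune(root, enc, np.arange(6))
        assert pruned.is_leaf  # 2 errors as leaf <= 3 as subtree
        assert pruned.prune_counts.tolist() == [4.0, 2.0]

    def test_retains_perfect_subtree(self):
        root = TreeNode(np.array([2.0, 2.0]), 0)
        root.feature_index = 0
        root.feature_name = "x"
        root.kind = "numeric"
        root.threshold = 0.5
        root.children = [TreeNode(np.array([2.0, 0.0]), 1), TreeNode(np.array([0.0, 2.0]), 1)]
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0, 0, 1, 1])
        enc = encode_single([x], ["numeric"], [0], y)
        pruned = reduced_error_prune(root, enc, np.arange(4))
        assert not pruned.is_leaf  # 0 subtree errors < 2 as leaf

    def test_no_pruning_config_keeps_tree(self, four_row_part):
        model = fit_reptree(four_row_part, REPTreeConfig(no_pruning=True))
        assert not model.root.is_leaf
        assert model.root.prune_counts.sum() == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_monotonicity(self, seed):
        """Pruning never increases hold-out error or node count."""
        rng = np.random.default_rng(seed)
        n = 80
        enc = encode_single(
            [rng.integers(0, 5, n), rng.integers(0, 3, n)],
            ["numeric", "nominal"], [0, 3], rng.integers(0, 2, n),
        )
        grow_idx, prune_idx = np.arange(0, 60), np.arange(60, n)
        root = grow_tree(enc, grow_idx, REPTreeConfig(min_num=1.0))
        before_nodes = root.node_count()

        def holdout_errors(node, idx):
            if node.is_leaf or idx.size == 0:
                return int((enc.y[idx] != node.predicted_class).sum())
            x = enc.cols[node.feature_index][idx]
            if node.kind == "numeric":
                groups = [idx[x < node.threshold], idx[x >= node.threshold]]
            else:
                groups = [idx[x == c] for c in range(len(node.categories))]
            return sum(holdout_errors(c, g) for c, g in zip(node.children, groups))

        before = holdout_errors(root, prune_idx)
        pruned = reduced_error_prune(copy.deepcopy(root), enc, prune_idx)
        # re-route on the pruned tree to count its errors
        after = holdout_errors(pruned, prune_idx)
        assert after <= before
        assert pruned.node_count() <= before_nodes


class TestFitPredict:
    def test_determinism_bit_identical(self, four_row_part):
        cfg = REPTreeConfig(no_pruning=True)
        m1 = fit_reptree(four_row_part, cfg)
        m2 = fit_reptree(four_row_part, cfg)
        assert m1.to_json(sort_keys=True) == m2.to_json(sort_keys=True)
        assert render_tree(m1) == render_tree(m2)

    def test_too_few_rows_for_pruning(self):
        part = single_target({"x": [1, 2]}, ["A", "B"])
        with pytest.raises(ValueError, match="num_folds"):
            fit_reptree(part, REPTreeConfig(num_folds=3))

    def test_single_leaf_predicts_everywhere(self):
        part = single_target({"x": [1, 2, 3]}, ["A", "A", "A"])
        model = fit_reptree(part, REPTreeConfig(no_pruning=True))
        assert model.root.is_leaf
        assert model.predict({"x": 99.0}) == "A"

    def test_threshold_routing(self, four_row_part):
        model = fit_reptree(four_row_part, REPTreeConfig(no_pruning=True))
        assert model.predict({"x": 1.7}) == "A"
        assert model.predict({"x": 3.0}) == "B"

    def test_missing_value_routes_to_heavier_child(self, four_row_part):
        """Child weights tie at 2 vs 2, so the first child (class A) wins."""
        model = fit_reptree(four_row_part, REPTreeConfig(no_pruning=True))
        assert model.predict({"x": None}) == "A"

    def test_distribution_smoothing(self):
        part = single_target({"x": [1, 1, 1, 2]}, ["A", "A", "A", "B"])
        model = fit_reptree(part, REPTreeConfig(no_pruning=True, max_depth=0))
        # single leaf with counts (3,1)
        np.testing.assert_allclose(model.predict_distribution({"x": 1}), [0.75, 0.25])
        smoothed = fit_reptree(
            part, REPTreeConfig(no_pruning=True, max_depth=0, initial_count=1.0)
        )
        np.testing.assert_allclose(
            smoothed.predict_distribution({"x": 1}), [4 / 6, 2 / 6]
        )

    @pytest.mark.parametrize("seed", [0, 7])
    def test_distribution_normalisation(self, seed):
        rng = np.random.default_rng(seed)
        part = single_target(
            {"x": rng.integers(0, 5, 60).tolist(), "z": rng.integers(0, 4, 60).tolist()},
            rng.choice(["A", "B", "C"], 60).tolist(),
            classes=("A", "B", "C"),
        )
        model = fit_reptree(part, REPTreeConfig())
        proba = model.predict_proba_frame(part.X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_schema_mismatch_raises(self, four_row_part):
        model = fit_reptree(four_row_part, REPTreeConfig(no_pruning=True))
        import pandas as pd

        with pytest.raises(ValueError, match="x"):
            model.predict_frame(pd.DataFrame({"other": [1.0]}))

    def test_serialization_round_trip(self, four_row_part):
        model = fit_reptree(four_row_part, REPTreeConfig())
        back = REPTreeModel.from_json(model.to_json())
        assert back.to_json(sort_keys=True) == model.to_json(sort_keys=True)
        assert render_tree(back) == render_tree(model)


class TestRenderTree:
    def _leaf_model(self, counts, prune, classes=("0", "1")):
        spec = LabelSpec("lab", tuple(classes), classes[-1] if len(classes) == 2 else None)
        node = TreeNode(np.array(counts, dtype=float), 0)
        node.prune_counts = np.array(prune, dtype=float)
        return REPTreeModel(
            node, REPTreeConfig(), spec, tuple(classes),
            (FeatureSpec("TR", "nominal", ("1", "2")),),
        )

    def test_published_leaf_annotation(self):
        """A leaf with 10 training instances (4 misclassified) and a 6-
        instance hold-out of 5 majority + 1 minority prints 0 (10/4) [5/1]."""
        model = self._leaf_model([6, 4], [5, 1])
        assert render_tree(model) == "0 (10/4) [5/1]"

    def test_unpruned_leaf_bracket_is_zero(self):
        model = self._leaf_model([3, 0], [0, 0])
        assert render_tree(model) == "0 (3/0) [0/0]"

    def test_holdout_error_bracket_switch(self):
        model = self._leaf_model([6, 4], [5, 1])
        assert render_tree(model, bracket="holdout_error") == "0 (10/4) [6/1]"

    def test_nominal_branch_lines(self):
        part = single_target(
            {"TR": ["1", "1", "2", "2"]}, ["A", "A", "B", "B"], kinds={"TR": "nominal"}
        )
        model = fit_reptree(part, REPTreeConfig(no_pruning=True))
        text = render_tree(model)
        assert "TR = 1" in text and "TR = 2" in text
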