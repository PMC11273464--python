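"""Metrics, cross-validation, report assembly, and method comparison.

Per-label rows report accuracy (percent), precision, true-negative rate,
ROC area, precision–recall area, recall, and F-score, plus an unweighted
"Average" row across labels (macro-averaging).  Binary labels use the
standard confusion-matrix formulas with the zero-denominator convention of
returning 0 (with a warning); multi-class labels use one-vs-rest values
averaged with class-prevalence weights.  Method comparison covers
improvement-over-baseline arithmetic and two nonparametric rank tests
(Mann–Whitney U with exact enumeration for small tie-free samples, and the
Quade blocked test in Conover's formulation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datasets import MultiLabelDataset, SingleTargetDataset
from .reptree import REPTreeConfig, fit_reptree

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "LabelMetrics",
    "DatasetReport",
    "RankTestResult",
    "ComparisonResult",
    "confusion_from_predictions",
    "binary_metrics",
    "multiclass_metrics",
    "roc_auc",
    "prc_auc",
    "stratified_kfold_indices",
    "cross_validate_fmll",
    "macro_average",
    "improvement_over_baselines",
    "mann_whitney_u",
    "quade_test",
]


# ---------------------------------------------------------------------------
# Confusion counts and ratio metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from binary (0/1) outcome vectors."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-d vectors")
    if t.size == 0:
        raise ValueError("empty prediction vectors")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("zero denominator in %s; reporting 0 by convention", name)
        return 0.0
    return num / den


def binary_metrics(c: ConfusionCounts) -> dict[str, float]:
    """ACC, PR, TPR (recall), FS, TNR and FPR from confusion counts, all on
    the 0–1 scale; zero-denominator ratios are 0 by convention."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    acc = (c.tp + c.tn) / c.total
    pr = _ratio(c.tp, c.tp + c.fp, "precision")
    tpr = _ratio(c.tp, c.tp + c.fn, "recall")
    fs = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f_score")
    tnr = _ratio(c.tn, c.tn + c.fp, "tnr")
    fpr = _ratio(c.fp, c.fp + c.tn, "fpr")
    return {"accuracy": acc, "precision": pr, "recall": tpr, "f_score": fs,
            "tnr": tnr, "fpr": fpr}


def multiclass_metrics(y_true, y_pred, classes: Sequence[str]) -> dict[str, float]:
    """Accuracy plus prevalence-weighted one-vs-rest precision/recall/F/TNR
    over the declared class inventory."""
    t = np.asarray(y_true, dtype=object)
    p = np.asarray(y_pred, dtype=object)
    if t.shape != p.shape:
        raise ValueError("length mismatch")
    class_set = set(classes)
    bad = (set(t) | set(p)) - class_set
    if bad:
        raise ValueError(f"unknown class value(s) {sorted(map(str, bad))}")
    n = t.size
    acc = float((t == p).mean())
    out = {"accuracy": acc, "precision": 0.0, "recall": 0.0, "f_score": 0.0,
           "tnr": 0.0, "fpr": 0.0}
    for cls in classes:
        weight = float((t == cls).mean())
        if weight == 0:
            continue
        c = confusion_from_predictions((t == cls).astype(int), (p == cls).astype(int))
        m = binary_metrics(c)
        for k in ("precision", "recall", "f_score", "tnr", "fpr"):
            out[k] += weight * m[k]
    return out


# ---------------------------------------------------------------------------
# Ranking curve areas
# ---------------------------------------------------------------------------


def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) formulation:
    P(score_pos > score_neg) + 0.5 P(tie)."""
    t = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = sps.rankdata(s)  # midranks for ties
    r_pos = ranks[t == 1].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _sweep_points(t: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(recall, precision) at every distinct score threshold of a
    descending-score sweep with ties grouped."""
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = t[order]
    cum_tp = np.cumsum(t_sorted == 1)
    cum_fp = np.cumsum(t_sorted == 0)
    # last index of each tie group
    last = np.nonzero(np.append(s_sorted[1:] != s_sorted[:-1], True))[0]
    tp = cum_tp[last]
    fp = cum_fp[last]
    n_pos = cum_tp[-1]
    recall = tp / n_pos
    precision = tp / (tp + fp)
    return recall, precision


def prc_auc(y_true, scores) -> float:
    """Area under the precision–recall curve: trapezoidal integration over
    the tie-grouped sweep points, anchored at recall 0 with the first
    group's precision."""
    t = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if int((t == 1).sum()) == 0:
        raise ValueError("prc_auc needs at least one positive")
    recall, precision = _sweep_points(t, s)
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[precision[0]], precision])
    return float(np.trapezoid(p, r))


def _weighted_ovr_area(y_true, score_matrix, classes, fn) -> float:
    """Class-prevalence-weighted one-vs-rest curve area for a multi-class
    label; classes absent from the truth carry zero weight."""
    t = np.asarray(y_true, dtype=object)
    m = np.asarray(score_matrix, dtype=float)
    out = 0.0
    for j, cls in enumerate(classes):
        weight = float((t == cls).mean())
        if weight == 0:
            continue
        truth = (t == cls).astype(int)
        try:
            area = fn(truth, m[:, j])
        except ValueError:
            logger.warning("undefined curve area for class %r; reporting 0", cls)
            area = 0.0
        out += weight * area
    return out


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def stratified_kfold_indices(n: int, target, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint test-index groups partitioning 0..n−1.

    Fold sizes differ by at most one with the first ``n mod k`` folds
    larger; within every class the members are spread as evenly as possible
    (per-fold class proportions deviate from the global ones by at most one
    instance).  The within-class orders are shuffled by ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k must not exceed n")
    target = np.asarray(target, dtype=object)
    if target.size != n:
        raise ValueError("target length must equal n")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    pointer = 0
    for cls in pd.unique(target):
        members = np.nonzero(target == cls)[0]
        members = members[rng.permutation(members.size)]
        for idx in members:
            folds[pointer % k].append(int(idx))
            pointer += 1
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


@dataclass(frozen=True)
class LabelMetrics:
    """One report row: accuracy in percent, the rest on the 0–1 scale."""

    label: str
    accuracy: float
    precision: float
    tnr: float
    roc_area: float
    prc_area: float
    recall: float
    f_score: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.accuracy, self.precision, self.tnr, self.roc_area,
                self.prc_area, self.recall, self.f_score)


_COLUMNS = ("Accuracy", "Precision", "TNR", "ROC", "PRC", "Recall", "F-Score")


@dataclass
class DatasetReport:
    """Per-label metric rows plus the unweighted Average row."""

    name: str
    rows: list[LabelMetrics]

    @property
    def average(self) -> LabelMetrics:
        cols = np.array([r.as_tuple() for r in self.rows], dtype=float)
        means = cols.mean(axis=0)
        return LabelMetrics("Average", *means)

    def to_frame(self, include_average: bool = True) -> pd.DataFrame:
        rows = self.rows + ([self.average] if include_average else [])
        return pd.DataFrame(
            [r.as_tuple() for r in rows],
            index=[r.label for r in rows],
            columns=list(_COLUMNS),
        )

    def to_text(self) -> str:
        """Rendering with accuracy at 2 decimals and rates at 3."""
        frame = self.to_frame()
        widths = max(12, max(len(i) for i in frame.index) + 2)
        lines = [f"{self.name}".ljust(widths) + "  ".join(f"{c:>9}" for c in _COLUMNS)]
        for label, row in frame.iterrows():
            cells = [f"{row['Accuracy']:9.2f}"] + [
                f"{row[c]:9.3f}" for c in _COLUMNS[1:]
            ]
            lines.append(label.ljust(widths) + "  ".join(cells))
        return "\n".join(lines)

    def to_csv(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label=self.name)


def _label_row(
    label_name: str,
    classes: Sequence[str],
    positive: str | None,
    y_true: np.ndarray,
    y_pred: np.ndarray,
    proba: np.ndarray,
) -> LabelMetrics:
    """Assemble one report row from pooled predictions for a label."""
    if len(classes) == 2 and positive is not None:
        t = (y_true == positive).astype(int)
        p = (y_pred == positive).astype(int)
        m = binary_metrics(confusion_from_predictions(t, p))
        pos_col = list(classes).index(positive)
        scores = proba[:, pos_col]
        try:
            roc = roc_auc(t, scores)
        except ValueError:
            logger.warning("single-class truth for %r; ROC reported 0", label_name)
            roc = 0.0
        prc = prc_auc(t, scores) if t.sum() else 0.0
    else:
        m = multiclass_metrics(y_true, y_pred, classes)
        roc = _weighted_ovr_area(y_true, proba, classes, roc_auc)
        prc = _weighted_ovr_area(y_true, proba, classes, prc_auc)
    return LabelMetrics(
        label=label_name,
        accuracy=100.0 * m["accuracy"],
        precision=m["precision"],
        tnr=m["tnr"],
        roc_area=roc,
        prc_area=prc,
        recall=m["recall"],
        f_score=m["f_score"],
    )


def cross_validate_fmll(
    dataset: MultiLabelDataset,
    config: REPTreeConfig | None = None,
    k: int = 10,
    seed: int = 1,
    mode: str = "auto",
    shared_folds: bool = False,
) -> DatasetReport:
    """Stratified k-fold cross-validation of the federated multi-label
    pipeline, one metric row per label plus the Average row.

    Folds are drawn independently per label, each stratified on its own
    target (``shared_folds=True`` reuses the first label's folds for all).
    Test predictions are pooled over folds before the metrics are computed,
    so every label's row summarises exactly N predictions.
    """
    from .datasets import decompose  # local import to avoid cycle noise

    config = config or REPTreeConfig()
    if mode == "auto":
        mode = "strict_binary" if all(l.is_binary for l in dataset.labels) else "per_label"
    parts = decompose(dataset, mode)
    n = dataset.n_samples
    rows: list[LabelMetrics] = []
    shared: list[np.ndarray] | None = None
    for part in parts:
        target_vals = part.y.to_numpy()
        if shared_folds:
            if shared is None:
                shared = stratified_kfold_indices(n, target_vals, k, seed)
            folds = shared
        else:
            folds = stratified_kfold_indices(n, target_vals, k, seed)
        classes = part.target_classes
        y_true = np.empty(n, dtype=object)
        y_pred = np.empty(n, dtype=object)
        proba = np.zeros((n, len(classes)))
        for test_idx in folds:
            mask = np.zeros(n, dtype=bool)
            mask[test_idx] = True
            train_part = SingleTargetDataset(
                part.source_label,
                part.features,
                part.X.iloc[~mask].reset_index(drop=True),
                part.y.iloc[~mask].reset_index(drop=True),
                part.mode,
            )
            model = fit_reptree(train_part, config)
            X_test = part.X.iloc[test_idx]
            y_pred[test_idx] = model.predict_frame(X_test)
            proba[test_idx] = model.predict_proba_frame(X_test)
            if part.mode == "strict_binary":
                y_true[test_idx] = part.y.iloc[test_idx].astype(str).to_numpy()
            else:
                y_true[test_idx] = part.y.iloc[test_idx].to_numpy()
        positive = "1" if part.mode == "strict_binary" else part.source_label.positive
        rows.append(
            _label_row(part.source_label.name, classes, positive, y_true, y_pred, proba)
        )
    return DatasetReport(dataset.name, rows)


# ---------------------------------------------------------------------------
# Macro average and baseline comparison
# ---------------------------------------------------------------------------


def macro_average(values: Iterable[float]) -> float:
    """Unweighted arithmetic mean across labels (the report's Average row)."""
    vals = list(values)
    if not vals:
        raise ValueError("macro_average of an empty collection")
    return float(np.mean(vals))


@dataclass(frozen=True)
class ComparisonResult:
    proposed: float
    baselines: tuple[float, ...]
    baseline_mean: float
    improvement: float  # proposed − baseline mean, in reporting units


def improvement_over_baselines(
    proposed: float, baselines: Iterable[float], as_points: bool | None = None
) -> ComparisonResult:
    """Difference between a proposed value and the unweighted baseline mean.

    When the inputs are rates on the 0–1 scale the improvement is reported
    in percentage points (×100); pass ``as_points`` to force either
    behaviour.
    """
    base = tuple(float(b) for b in baselines)
    if not base:
        raise ValueError("baselines must be non-empty")
    mean = float(np.mean(base))
    diff = float(proposed) - mean
    if as_points is None:
        as_points = abs(proposed) <= 1.0 and all(abs(b) <= 1.0 for b in base)
    return ComparisonResult(
        proposed=float(proposed),
        baselines=base,
        baseline_mean=mean,
        improvement=diff * 100.0 if as_points else diff,
    )


# ---------------------------------------------------------------------------
# Nonparametric rank tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankTestResult:
    test: str  # "mann_whitney_u" | "quade"
    statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx" | "f_distribution"
    sidedness: str = "two-sided"
    df: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def mann_whitney_u(
    a, b, sidedness: str = "two-sided", method: str = "auto"
) -> RankTestResult:
    """Mann–Whitney U test with midranks for ties.

    ``method="exact"`` enumerates every assignment of the pooled values to
    the two groups (feasible for small samples); ``auto`` picks exact when
    n+m ≤ 12 and the pooled values are tie-free, else the normal
    approximation with tie and continuity corrections.  The two-sided exact
    p-value is the probability of a U at least as far from the null mean
    nm/2 as observed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if sidedness not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    u_obs = _u_statistic(a, b)
    if method == "auto":
        method = "exact" if (n + m <= 12 and not has_ties) else "normal_approx"

    if method == "exact":
        ranks = sps.rankdata(pooled)
        total = 0
        count_ge = 0
        count_le = 0
        center = n * m / 2.0
        dev_obs = abs(u_obs - center)
        count_dev = 0
        for combo in combinations(range(n + m), n):
            r_a = ranks[list(combo)].sum()
            u = r_a - n * (n + 1) / 2.0
            total += 1
            if u >= u_obs:
                count_ge += 1
            if u <= u_obs:
                count_le += 1
            if abs(u - center) >= dev_obs - 1e-12:
                count_dev += 1
        if sidedness == "two-sided":
            p = count_dev / total
        elif sidedness == "greater":
            p = count_ge / total
        else:
            p = count_le / total
        return RankTestResult("mann_whitney_u", u_obs, min(1.0, p), "exact", sidedness)

    # normal approximation with tie correction and continuity correction
    N = n + m
    mean_u = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_u = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var_u <= 0:
        raise ValueError("degenerate sample: all pooled values identical")
    sd = math.sqrt(var_u)
    if sidedness == "two-sided":
        z = (abs(u_obs - mean_u) - 0.5) / sd
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    elif sidedness == "greater":
        z = (u_obs - mean_u - 0.5) / sd
        p = sps.norm.sf(z)
    else:
        z = (u_obs - mean_u + 0.5) / sd
        p = sps.norm.cdf(z)
    return RankTestResult(
        "mann_whitney_u", u_obs, float(min(1.0, max(p, np.nextafter(0, 1)))),
        "normal_approx", sidedness
    )


def quade_test(blocks) -> RankTestResult:
    """Quade blocked rank test (Conover's formulation).

    ``blocks`` is a b×k table (b blocks, k treatments).  Within-block ranks
    r_ij are weighted by Q_i, the rank of block i's range, giving
    S_ij = Q_i (r_ij − (k+1)/2); the statistic
    F = (b−1)·B/(A−B) with A = Σ S_ij² and B = (1/b) Σ_j S_j² is referred
    to the F distribution with (k−1, (b−1)(k−1)) degrees of freedom.
    """
    table = np.asarray(blocks, dtype=float)
    if table.ndim != 2:
        raise ValueError("blocks must be a 2-d table")
    b, k = table.shape
    if b < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    ranges = table.max(axis=1) - table.min(axis=1)
    if np.all(ranges == 0):
        raise ValueError("degenerate table: all within-block values equal")
    r = np.apply_along_axis(sps.rankdata, 1, table)
    q = sps.rankdata(ranges)
    s = q[:, None] * (r - (k + 1) / 2.0)
    a_stat = float((s**2).sum())
    col_sums = s.sum(axis=0)
    b_stat = float((col_sums**2).sum()) / b
    df = (k - 1, (b - 1) * (k - 1))
    if a_stat == b_stat:
        # perfect ordering in every block: F is infinite, p is the
        # permutation bound 1/k!^(b-1) (Conover's convention)
        p = 1.0 / math.factorial(k) ** (b - 1)
        return RankTestResult("quade", float("inf"), p, "f_distribution", "two-sided", df)
    f_stat = (b - 1) * b_stat / (a_stat - b_stat)
    p = float(sps.f.sf(f_stat, *df))
    return RankTestResult(
        "quade", float(f_stat), float(min(1.0, max(p, np.nextafter(0, 1)))),
        "f_distribution", "two-sided", df
    )
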