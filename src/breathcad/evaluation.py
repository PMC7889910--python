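"""Data splitting, confusion matrices, precision/recall/F-score/accuracy, ROC/AUC.

Metrics follow the one-vs-rest convention for the three classes (EGC=0, AGC=1,
HEALTHY=2): precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R),
multiclass accuracy = trace/total.  Degenerate 0/0 ratios surface as NaN (a
flagged null in exports), never as a silent zero.  ROC curves are computed by a
threshold sweep with trapezoidal AUC, which equals the Mann-Whitney concordance
probability with ties counted one half.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spectra import ClassLabel

__all__ = [
    "SplitSpec",
    "split_data",
    "ConfusionMatrix",
    "confusion",
    "binary_counts",
    "precision",
    "recall",
    "f_score",
    "accuracy",
    "ROCCurve",
    "roc_curve",
    "MetricsReport",
    "evaluate",
]


# ---------------------------------------------------------------------------
# Splitting.
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Train/validation/test fractions (default 0.70/0.15/0.15), stratified."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if len(self.fractions) != 3:
            raise ValueError("exactly three fractions required")
        if any(f < 0 or f > 1 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def _partition_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    # floor(n * fraction), remainders assigned train-first
    sizes = [int(math.floor(n * f)) for f in fractions]
    leftover = n - sum(sizes)
    i = 0
    while leftover > 0:
        sizes[i % 3] += 1
        leftover -= 1
        i += 1
    return sizes


def split_data(labels: Sequence[int], spec: SplitSpec | None = None,
               groups: Sequence | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, validation, test) index arrays.

    With ``groups`` given (e.g. the source sample id of augmented copies), all
    members of a group land in the same partition — the leakage guard for
    augmented cohorts.  Global partition sizes follow floor(n*fraction) with
    remainders assigned train-first; stratification keeps per-class proportions
    within one sample per partition while preserving those global sizes.
    """
    spec = spec or SplitSpec()
    spec.validate()
    labels = np.asarray(labels, dtype=int)

    if groups is not None:
        groups = np.asarray(groups)
        uniq, first_idx = np.unique(groups, return_index=True)
        group_labels = []
        for g, fi in zip(uniq, first_idx):
            members = labels[groups == g]
            if np.unique(members).size > 1:
                raise ValueError(f"group {g!r} mixes class labels")
            group_labels.append(labels[fi])
        tr_g, va_g, te_g = split_data(group_labels,
                                      SplitSpec(spec.fractions, spec.stratified, spec.seed))
        def expand(gidx):
            sel = np.isin(groups, uniq[gidx])
            return np.flatnonzero(sel)
        return expand(tr_g), expand(va_g), expand(te_g)

    n = labels.size
    positive = [f > 0 for f in spec.fractions]
    targets = _partition_sizes(n, spec.fractions)
    for f, size in zip(spec.fractions, targets):
        if f > 0 and size == 0:
            raise ValueError(f"fraction {f} yields zero samples for n={n}")
    rng = np.random.default_rng(spec.seed)

    if not spec.stratified:
        perm = rng.permutation(n)
        tr = perm[:targets[0]]
        va = perm[targets[0]:targets[0] + targets[1]]
        te = perm[targets[0] + targets[1]:]
        return np.sort(tr), np.sort(va), np.sort(te)

    classes = np.unique(labels)
    # per-class floors, then apportion leftovers under the global capacities
    alloc = {c: [int(math.floor(np.sum(labels == c) * f)) for f in spec.fractions]
             for c in classes}
    capacity = [targets[p] - sum(alloc[c][p] for c in classes) for p in range(3)]
    for c in classes:
        leftover = int(np.sum(labels == c)) - sum(alloc[c])
        used: set[int] = set()
        for _ in range(leftover):
            choices = [p for p in range(3)
                       if capacity[p] > 0 and positive[p] and p not in used]
            if not choices:
                choices = [p for p in range(3) if capacity[p] > 0]
            p = choices[0]
            alloc[c][p] += 1
            capacity[p] -= 1
            used.add(p)

    parts: list[list[int]] = [[], [], []]
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        a, b = alloc[c][0], alloc[c][0] + alloc[c][1]
        parts[0].extend(idx[:a])
        parts[1].extend(idx[a:b])
        parts[2].extend(idx[b:])
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)  # type: ignore


# ---------------------------------------------------------------------------
# Confusion matrix and scalar metrics.
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """3x3 counts, rows = true class, columns = predicted (EGC, AGC, HEALTHY)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size != y_pred.size:
        raise ValueError("label arrays must have equal length")
    if y_true.size == 0:
        raise ValueError("empty label arrays")
    for arr in (y_true, y_pred):
        if arr.min() < 0 or arr.max() > 2:
            raise ValueError("labels must be class codes 0, 1 or 2")
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def binary_counts(cm: ConfusionMatrix, positive: int) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) for the one-vs-rest collapse of the named class."""
    c = int(positive)
    tp = int(cm.counts[c, c])
    fn = int(cm.counts[c, :].sum() - tp)
    fp = int(cm.counts[:, c].sum() - tp)
    tn = int(cm.total - tp - fn - fp)
    return tp, tn, fp, fn


def precision(tp: int, fp: int) -> float:
    """TP/(TP+FP); NaN flags the undefined 0/0 case."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be nonnegative")
    return float("nan") if tp + fp == 0 else tp / (tp + fp)


def recall(tp: int, fn: int) -> float:
    """TP/(TP+FN); NaN flags the undefined 0/0 case."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be nonnegative")
    return float("nan") if tp + fn == 0 else tp / (tp + fn)


def f_score(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); NaN when undefined (either input NaN or P=R=0)."""
    if math.isnan(p) or math.isnan(r):
        return float("nan")
    if p + r == 0:
        return float("nan")
    return 2.0 * p * r / (p + r)


def accuracy(cm: ConfusionMatrix) -> float:
    """Multiclass accuracy: trace/total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


# ---------------------------------------------------------------------------
# ROC / AUC.
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores: Sequence[float], y_true: Sequence[int],
              positive: int) -> ROCCurve:
    """One-vs-rest ROC by threshold sweep; trapezoidal AUC (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true, dtype=int) == int(positive)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative sample")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    # indices at the end of each tie block
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    block_ends = np.concatenate((distinct, [s_sorted.size - 1]))
    tps = np.cumsum(y_sorted)[block_ends]
    fps = np.cumsum(~y_sorted)[block_ends]
    tpr = np.concatenate(([0.0], tps / n_pos))
    fpr = np.concatenate(([0.0], fps / n_neg))
    thresholds = np.concatenate(([np.inf], s_sorted[block_ends]))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr,
                    auc=float(np.trapezoid(tpr, fpr)))


# ---------------------------------------------------------------------------
# Aggregated report.
# ---------------------------------------------------------------------------

def _null(x: float) -> float | None:
    return None if (x is None or (isinstance(x, float) and math.isnan(x))) else float(x)


@dataclass
class MetricsReport:
    """Per-class and aggregate classification metrics for one partition."""

    confusion: ConfusionMatrix
    per_class: dict = field(default_factory=dict)
    accuracy: float = float("nan")
    macro_precision: float = float("nan")
    macro_recall: float = float("nan")
    macro_f_score: float = float("nan")
    macro_auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.counts.tolist(),
            "accuracy": self.accuracy,
            "macro_precision": _null(self.macro_precision),
            "macro_recall": _null(self.macro_recall),
            "macro_f_score": _null(self.macro_f_score),
            "macro_auc": _null(self.macro_auc) if self.macro_auc is not None else None,
            "per_class": {
                name: {k: (_null(v) if isinstance(v, float) else v)
                       for k, v in stats.items()}
                for name, stats in self.per_class.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                             probs: np.ndarray | None) -> MetricsReport:
    cm = confusion(y_true, y_pred)
    per_class: dict = {}
    precisions, recalls, fs, aucs = [], [], [], []
    for cls in ClassLabel:
        tp, tn, fp, fn = binary_counts(cm, int(cls))
        p = precision(tp, fp)
        r = recall(tp, fn)
        f = f_score(p, r)
        stats = {"tp": tp, "tn": tn, "fp": fp, "fn": fn,
                 "precision": p, "recall": r, "f_score": f,
                 "precision_defined": not math.isnan(p),
                 "recall_defined": not math.isnan(r),
                 "f_score_defined": not math.isnan(f)}
        auc_val = None
        if probs is not None:
            has_pos = np.any(y_true == int(cls))
            has_neg = np.any(y_true != int(cls))
            if has_pos and has_neg:
                auc_val = roc_curve(probs[:, int(cls)], y_true, int(cls)).auc
                aucs.append(auc_val)
        stats["auc"] = auc_val
        per_class[cls.name] = stats
        precisions.append(p)
        recalls.append(r)
        fs.append(f)
    with np.errstate(invalid="ignore"):
        macro = lambda vals: float(np.nanmean(vals)) if not all(
            math.isnan(v) for v in vals) else float("nan")
    return MetricsReport(
        confusion=cm,
        per_class=per_class,
        accuracy=accuracy(cm),
        macro_precision=macro(precisions),
        macro_recall=macro(recalls),
        macro_f_score=macro(fs),
        macro_auc=float(np.mean(aucs)) if aucs else None,
    )


def evaluate(model, X: np.ndarray, y: Sequence[int],
             partitions: Mapping[str, Sequence[int]]) -> dict[str, MetricsReport]:
    """Reports per partition plus the pooled report under key ``"all"``.

    ``model`` is anything exposing ``predict`` (class codes) and, optionally,
    ``predict_proba`` (for per-class one-vs-rest AUC).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    reports: dict[str, MetricsReport] = {}
    all_idx: list[int] = []
    for name, idx in partitions.items():
        idx = np.asarray(idx, dtype=int)
        all_idx.extend(idx.tolist())
        probs = model.predict_proba(X[idx]) if hasattr(model, "predict_proba") else None
        reports[name] = _report_from_predictions(y[idx], np.asarray(model.predict(X[idx])),
                                                 probs)
    idx = np.array(sorted(set(all_idx)), dtype=int)
    probs = model.predict_proba(X[idx]) if hasattr(model, "predict_proba") else None
    reports["all"] = _report_from_predictions(y[idx], np.asarray(model.predict(X[idx])),
                                              probs)
    return reports
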