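"""Binary-classification metrics and evaluation protocols.

Metrics are the confusion-table family standard in site-prediction
benchmarking — Recall (sensitivity), Specificity, Accuracy, Matthews
correlation coefficient, Precision and F1 — plus AUROC computed as the
Mann-Whitney rank statistic (probability that a random positive
outranks a random negative, ties counted one half).

Three protocols are provided: repeated stratified k-fold
cross-validation (default 10 folds x 10 repeats), leave-one-out (LOO,
pooled into a single confusion table), and a stratified hold-out split
(default 30% test).  Any ratio with a zero denominator is reported as
NaN with a warning rather than silently coerced to 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .encode import FeatureMatrix
from .stack import StackingConfig, fit_stacking

METRIC_ORDER = ("acc", "mcc", "recall", "sp", "precision", "f1", "auroc")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN cell counts of a binary confusion table."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Confusion counts from true 0/1 labels and hard 0/1 predictions."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if len(y) != len(p):
        raise ValueError(f"{len(y)} labels but {len(p)} predictions")
    if len(y) == 0:
        raise ValueError("empty input")
    if not (set(np.unique(y)) <= {0, 1} and set(np.unique(p)) <= {0, 1}):
        raise ValueError("labels and predictions must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return math.nan
    return num / den


@dataclass
class MetricsReport:
    """Confusion-derived metrics (plus AUROC when scores are available)."""

    recall: float
    sp: float
    acc: float
    mcc: float
    precision: float
    f1: float
    counts: ConfusionCounts
    auroc: float = math.nan
    threshold: float = 0.5

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in METRIC_ORDER}
        d["counts"] = vars(self.counts)
        d["threshold"] = self.threshold
        return d


def metrics(counts: ConfusionCounts, threshold: float = 0.5) -> MetricsReport:
    """Compute Recall, Sp, Acc, MCC, Precision and F1 from cell counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP)); any
    metric whose denominator is zero comes back as NaN with a warning.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    recall = _ratio(tp, tp + fn, "recall")
    sp = _ratio(tn, tn + fp, "specificity")
    acc = (tp + tn) / counts.total
    precision = _ratio(tp, tp + fp, "precision")
    denom = math.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fn) * float(tn + fp)
    )
    mcc = _ratio(tp * tn - fp * fn, denom, "mcc")
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = _ratio(0, 0, "f1")  # harmonic mean undefined
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(recall, sp, acc, mcc, precision, f1, counts, threshold=threshold)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a uniformly chosen positive receives a
    higher score than a uniformly chosen negative, counting ties as one
    half; invariant under strictly monotone transforms of the scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(s) != len(y):
        raise ValueError("scores and labels must be parallel")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluate_predictions(
    labels: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
) -> MetricsReport:
    """Threshold scores, build the confusion table and attach AUROC."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    rep = metrics(confusion(y, (s >= threshold).astype(int)), threshold)
    rep.auroc = auroc(s, y)
    return rep


# ---------------------------------------------------------------------------
# Protocols


@dataclass
class CVResult:
    """Per-fold metric reports plus pooled and mean/sd aggregates."""

    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    protocol: dict = field(default_factory=dict)

    def mean(self, metric: str) -> float:
        vals = [getattr(r, metric) for r in self.fold_reports]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    def sd(self, metric: str) -> float:
        vals = [getattr(r, metric) for r in self.fold_reports]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else math.nan

    def summary_frame(self) -> pd.DataFrame:
        """One row per aggregate (mean, sd, pooled), benchmark column order."""
        rows = {
            "mean": {m: self.mean(m) for m in METRIC_ORDER},
            "sd": {m: self.sd(m) for m in METRIC_ORDER},
            "pooled": {m: getattr(self.pooled, m) for m in METRIC_ORDER},
        }
        return pd.DataFrame(rows).T[list(METRIC_ORDER)]

    def as_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "mean": {m: self.mean(m) for m in METRIC_ORDER},
            "sd": {m: self.sd(m) for m in METRIC_ORDER},
            "pooled": self.pooled.as_dict(),
            "folds": [r.as_dict() for r in self.fold_reports],
        }


ModelFactory = Callable[[np.ndarray, np.ndarray, int], object]


def _default_factory(config: StackingConfig, columns: list[str]):
    """Model factory closing over a stacking config."""

    def factory(X: np.ndarray, y: np.ndarray, seed: int):
        fm = FeatureMatrix(pd.DataFrame(X, columns=columns))
        return fit_stacking(fm, y, config, seed=seed)

    def score(model, X: np.ndarray) -> np.ndarray:
        fm = FeatureMatrix(pd.DataFrame(X, columns=columns))
        return model.predict_proba(fm)

    return factory, score


def cross_validate(
    matrix: FeatureMatrix,
    labels: np.ndarray | Sequence[int],
    config: StackingConfig,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVResult:
    """Repeated stratified k-fold CV of a stacked ensemble.

    Folds are re-randomized per repeat from ``seed``; a fresh stack is
    fit on every training fold; per-fold metrics use ``threshold`` and
    fold AUROC comes from the held-out probabilities.  The pooled report
    aggregates all held-out predictions of all repeats into one table.
    """
    factory, score = _default_factory(config, matrix.columns)
    return cross_validate_factory(
        matrix.X, np.asarray(labels, dtype=int), factory, score,
        folds=folds, repeats=repeats, seed=seed, threshold=threshold,
    )


def cross_validate_factory(
    X: np.ndarray,
    y: np.ndarray,
    factory: ModelFactory,
    score: Callable[[object, np.ndarray], np.ndarray],
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVResult:
    """CV harness over any (fit, score) pair; used by the IFS strategies."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes for cross-validation")
    if folds > counts.min():
        raise ValueError(f"folds={folds} exceeds smallest class count {counts.min()}")
    fold_reports: list[MetricsReport] = []
    all_scores = np.empty(0)
    all_labels = np.empty(0, dtype=int)
    for r in range(repeats):
        rep_seed = (seed * 7919 + r) % (2**31 - 1)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        for train_idx, test_idx in skf.split(X, y):
            model = factory(X[train_idx], y[train_idx], rep_seed)
            proba = np.asarray(score(model, X[test_idx]), dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tiny folds may miss a class cell
                rep_metrics = metrics(
                    confusion(y[test_idx], (proba >= threshold).astype(int)), threshold
                )
                if len(np.unique(y[test_idx])) == 2:
                    rep_metrics.auroc = auroc(proba, y[test_idx])
            fold_reports.append(rep_metrics)
            all_scores = np.concatenate([all_scores, proba])
            all_labels = np.concatenate([all_labels, y[test_idx]])
    pooled = evaluate_predictions(all_labels, all_scores, threshold)
    return CVResult(
        fold_reports,
        pooled,
        protocol={"protocol": "cv", "folds": folds, "repeats": repeats, "seed": seed},
    )


def loocv(
    matrix: FeatureMatrix,
    labels: np.ndarray | Sequence[int],
    config: StackingConfig,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVResult:
    """Leave-one-out evaluation: n fits, predictions pooled into one table.

    Per-fold metrics are meaningless at fold size 1, so only the pooled
    report is populated.
    """
    y = np.asarray(labels, dtype=int)
    X = matrix.X
    if len(y) < 2:
        raise ValueError("leave-one-out needs at least 2 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes")
    factory, score = _default_factory(config, matrix.columns)
    scores = np.empty(len(y))
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        model = factory(X[mask], y[mask], seed)
        scores[i] = score(model, X[[i]])[0]
    pooled = evaluate_predictions(y, scores, threshold)
    return CVResult([], pooled, protocol={"protocol": "loo", "n_fits": len(y), "seed": seed})


def holdout_split(
    matrix: FeatureMatrix,
    labels: np.ndarray | Sequence[int],
    test_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split (disjoint, exhaustive, seeded)."""
    y = np.asarray(labels, dtype=int)
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    for part, name in ((train_idx, "train"), (test_idx, "test")):
        if len(np.unique(y[part])) < 2:
            raise ValueError(f"{name} split lost a class; adjust fraction or n")
    return np.sort(train_idx), np.sort(test_idx)


def holdout_evaluate(
    matrix: FeatureMatrix,
    labels: np.ndarray | Sequence[int],
    config: StackingConfig,
    test_fraction: float = 0.3,
    seed: int = 0,
    threshold: float = 0.5,
) -> MetricsReport:
    """Fit on the stratified train part, report metrics on the held-out part."""
    y = np.asarray(labels, dtype=int)
    train_idx, test_idx = holdout_split(matrix, y, test_fraction, seed)
    train_fm = FeatureMatrix(matrix.data.iloc[train_idx], matrix.specs)
    test_fm = FeatureMatrix(matrix.data.iloc[test_idx], matrix.specs)
    model = fit_stacking(train_fm, y[train_idx], config, seed=seed)
    return evaluate_predictions(y[test_idx], model.predict_proba(test_fm), threshold)


def summary_tsv(results: dict[str, MetricsReport | CVResult]) -> str:
    """Benchmark-style TSV: one row per protocol/model, fixed column order."""
    lines = ["model\t" + "\t".join(m.upper() for m in METRIC_ORDER)]
    for name, res in results.items():
        rep = res.pooled if isinstance(res, CVResult) else res
        vals = "\t".join(f"{getattr(rep, m):.4f}" for m in METRIC_ORDER)
        lines.append(f"{name}\t{vals}")
    return "\n".join(lines) + "\n"
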