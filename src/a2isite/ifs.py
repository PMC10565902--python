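"""Incremental feature selection (IFS) for stacked ensembles.

Both strategies rank descriptors by a classifier's feature importance
and scan growing prefixes of the ranking with repeated stratified CV,
recording mean MCC and AUROC per prefix size k.  The optimal k
maximizes mean MCC, with mean AUROC breaking ties and the smallest k
breaking any remaining tie (parsimony).

Strategy 1 runs the scan independently per base classifier, retains one
optimal subset per classifier, and fits the final stacked model on the
union of those subsets.  Strategy 2 uses one global ranking (from the
ranking classifier, by default the base classifier with the best
standalone CV MCC), evaluates the full stacked model on every prefix,
and fits the final stack on the single optimal prefix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .encode import FeatureMatrix
from .evalkit import cross_validate, cross_validate_factory
from .stack import (
    BaseLearnerSpec,
    StackedModel,
    StackingConfig,
    feature_importance,
    fit_stacking,
    positive_probability,
)

#: Strategy retained per species.
SPECIES_STRATEGY = {"Hs": 2, "Mm": 1, "Dm": 1}


def species_selection_preset(species: str) -> int:
    """Feature-selection strategy id (1 or 2) retained for a species."""
    try:
        return SPECIES_STRATEGY[species]
    except KeyError:
        raise ValueError(
            f"no selection preset for species {species!r}; known: {sorted(SPECIES_STRATEGY)}"
        ) from None


def default_k_grid(m: int, max_points: int = 50) -> list[int]:
    """Prefix sizes to scan: every k for small m, else log-spaced.

    The full grid 1..m is kept when m <= ``max_points``; otherwise about
    ``max_points`` log-spaced values always including 1 and m.  A stride
    is a tractability concession: the scan re-runs repeated CV at every
    grid point.
    """
    if m < 1:
        raise ValueError("need at least one feature")
    if m <= max_points:
        return list(range(1, m + 1))
    ks = np.unique(np.round(np.geomspace(1, m, max_points)).astype(int))
    return sorted(set(ks.tolist()) | {1, m})


@dataclass(frozen=True)
class RankedFeatureList:
    """Descriptor names in descending importance, with their source."""

    features: tuple[str, ...]
    source: str

    def top(self, k: int) -> list[str]:
        if not 1 <= k <= len(self.features):
            raise ValueError(f"k={k} out of range [1, {len(self.features)}]")
        return list(self.features[:k])


@dataclass
class SelectionResult:
    """Curves, chosen prefix sizes and selected subsets of an IFS run."""

    strategy: int
    curves: dict[str, pd.DataFrame]  # per ranking source: k, mean/sd MCC, mean/sd AUC
    chosen_k: dict[str, int]
    subsets: dict[str, list[str]]
    selected: list[str]  # union (Strategy 1) or optimal prefix (Strategy 2)
    rankings: dict[str, RankedFeatureList]
    cv: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "strategy": self.strategy,
            "seed": self.seed,
            "cv": self.cv,
            "chosen_k": self.chosen_k,
            "subsets": self.subsets,
            "selected": self.selected,
            "curves": {
                name: df.to_dict(orient="records") for name, df in self.curves.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def curves_tsv(self, path: str | Path) -> None:
        frames = []
        for name, df in self.curves.items():
            d = df.copy()
            d.insert(0, "source", name)
            frames.append(d)
        pd.concat(frames).to_csv(path, sep="\t", index=False)


def _pick_optimal_k(curve: pd.DataFrame) -> int:
    """Max mean MCC; ties by max mean AUROC; remaining ties by smallest k."""
    best = curve.sort_values(
        by=["mean_mcc", "mean_auc", "k"], ascending=[False, False, True], kind="stable"
    )
    return int(best.iloc[0]["k"])


def _single_classifier_cv(
    X: np.ndarray,
    y: np.ndarray,
    spec: BaseLearnerSpec,
    folds: int,
    repeats: int,
    seed: int,
):
    def factory(Xtr, ytr, fold_seed):
        model = spec.build()
        model.fit(Xtr, ytr)
        return model

    return cross_validate_factory(
        X, y, factory, positive_probability, folds=folds, repeats=repeats, seed=seed
    )


def _scan_curve(matrix, y, k_grid, evaluate) -> pd.DataFrame:
    rows = []
    for k in k_grid:
        res = evaluate(k)
        rows.append(
            {
                "k": k,
                "mean_mcc": res.mean("mcc"),
                "sd_mcc": res.sd("mcc"),
                "mean_auc": res.mean("auroc"),
                "sd_auc": res.sd("auroc"),
            }
        )
    return pd.DataFrame(rows)


def ifs_strategy1(
    matrix: FeatureMatrix,
    labels: np.ndarray | Sequence[int],
    config: StackingConfig,
    k_grid: Sequence[int] | None = None,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> tuple[StackedModel, SelectionResult]:
    """Per-classifier IFS; final stack on the union of optimal subsets.

    For every base classifier: rank descriptors by its own importance,
    CV-evaluate that single classifier on each prefix in ``k_grid``,
    keep the optimal prefix.  The stacked model is then fit (same
    config, same seed) on the union of the per-classifier subsets,
    ordered as in the original matrix.
    """
    y = np.asarray(labels, dtype=int)
    m = len(matrix.columns)
    k_grid = sorted(k_grid) if k_grid is not None else default_k_grid(m)
    if not k_grid:
        raise ValueError("empty k grid")
    if k_grid[0] < 1 or k_grid[-1] > m:
        raise ValueError(f"k grid must lie within [1, {m}]")

    curves: dict[str, pd.DataFrame] = {}
    chosen_k: dict[str, int] = {}
    subsets: dict[str, list[str]] = {}
    rankings: dict[str, RankedFeatureList] = {}
    for i, spec in enumerate(config.base):
        name = f"{spec.algorithm}#{i}"
        ranked = RankedFeatureList(
            tuple(f for f, _ in feature_importance(spec, matrix, y)), name
        )
        rankings[name] = ranked

        def evaluate(k, _ranked=ranked, _spec=spec):
            sub = matrix.select(_ranked.top(k))
            return _single_classifier_cv(sub.X, y, _spec, folds, repeats, seed)

        curve = _scan_curve(matrix, y, k_grid, evaluate)
        curves[name] = curve
        k_opt = _pick_optimal_k(curve)
        chosen_k[name] = k_opt
        subsets[name] = ranked.top(k_opt)

    union = set().union(*subsets.values())
    selected = [c for c in matrix.columns if c in union]
    model = fit_stacking(matrix.select(selected), y, config, seed=seed)
    result = SelectionResult(
        strategy=1,
        curves=curves,
        chosen_k=chosen_k,
        subsets=subsets,
        selected=selected,
        rankings=rankings,
        cv={"folds": folds, "repeats": repeats},
        seed=seed,
    )
    return model, result


def ifs_strategy2(
    matrix: FeatureMatrix,
    labels: np.ndarray | Sequence[int],
    config: StackingConfig,
    ranking_classifier: BaseLearnerSpec | None = None,
    k_grid: Sequence[int] | None = None,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> tuple[StackedModel, SelectionResult]:
    """Global-ranking IFS; the full stack is evaluated on every prefix.

    The ranking classifier defaults to the base classifier with the best
    standalone CV MCC on the full matrix.  For every prefix size k the
    complete stacked ensemble is fit and cross-validated on the top-k
    descriptors; the final stack is fit on the optimal prefix.
    """
    y = np.asarray(labels, dtype=int)
    m = len(matrix.columns)
    k_grid = sorted(k_grid) if k_grid is not None else default_k_grid(m)
    if not k_grid:
        raise ValueError("empty k grid")
    if k_grid[0] < 1 or k_grid[-1] > m:
        raise ValueError(f"k grid must lie within [1, {m}]")

    if ranking_classifier is None:
        best_mcc, ranking_classifier = -np.inf, config.base[0]
        for spec in config.base:
            res = _single_classifier_cv(matrix.X, y, spec, folds, repeats, seed)
            if res.mean("mcc") > best_mcc:
                best_mcc, ranking_classifier = res.mean("mcc"), spec
    name = ranking_classifier.algorithm
    ranked = RankedFeatureList(
        tuple(f for f, _ in feature_importance(ranking_classifier, matrix, y)), name
    )

    def evaluate(k):
        sub = matrix.select(ranked.top(k))
        return cross_validate(sub, y, config, folds=folds, repeats=repeats, seed=seed)

    curve = _scan_curve(matrix, y, k_grid, evaluate)
    k_opt = _pick_optimal_k(curve)
    selected = ranked.top(k_opt)
    model = fit_stacking(matrix.select(selected), y, config, seed=seed)
    result = SelectionResult(
        strategy=2,
        curves={name: curve},
        chosen_k={name: k_opt},
        subsets={name: selected},
        selected=selected,
        rankings={name: ranked},
        cv={"folds": folds, "repeats": repeats},
        seed=seed,
    )
    return model, result
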