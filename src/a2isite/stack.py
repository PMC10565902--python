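"""Stacked-ensemble classifiers over descriptor matrices.

Stacked generalization: a set of base classifiers is trained on the
descriptor matrix and their positive-class probabilities become the
inputs of a meta-classifier.  To avoid the leakage of fitting base
learners on the rows they later score, meta-features are produced
out-of-fold: a seeded stratified K-fold split trains each base learner
K times and scores only the held-out rows.  The base learners are then
refit on all rows for deployment.

Six base algorithms are supported — extra trees (ET), random forest
(RF), gradient-boosted trees (tagged ``CatBoost``), logistic regression
(LR), ridge classification (Ridge) and linear discriminant analysis
(LDA) — with species presets matching the ensembles that performed best
per species.  All fits are deterministic given (data, config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from scipy.special import expit
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .encode import EncoderSpec, FeatureMatrix

ALGORITHMS = ("ET", "RF", "CatBoost", "LR", "Ridge", "LDA")
TREE_ALGORITHMS = frozenset({"ET", "RF", "CatBoost"})
LINEAR_ALGORITHMS = frozenset({"LR", "Ridge", "LDA"})


class SchemaMismatchError(ValueError):
    """Prediction-time descriptor schema differs from the training schema."""


@dataclass(frozen=True)
class BaseLearnerSpec:
    """One of the six base algorithms plus hyperparameters and a seed."""

    algorithm: str
    hyperparams: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; supported: {ALGORITHMS}"
            )
        object.__setattr__(self, "hyperparams", dict(self.hyperparams))

    def build(self):
        """Instantiate the (unfitted) sklearn estimator."""
        hp = dict(self.hyperparams)
        if self.algorithm == "ET":
            return ExtraTreesClassifier(random_state=self.seed, n_jobs=1, **hp)
        if self.algorithm == "RF":
            return RandomForestClassifier(random_state=self.seed, n_jobs=1, **hp)
        if self.algorithm == "CatBoost":
            # Gradient-boosted decision trees back this tag; they expose the
            # impurity feature importances the selection strategies need.
            return GradientBoostingClassifier(random_state=self.seed, **hp)
        if self.algorithm == "LR":
            hp.setdefault("max_iter", 2000)
            return LogisticRegression(random_state=self.seed, **hp)
        if self.algorithm == "Ridge":
            return RidgeClassifier(random_state=self.seed, **hp)
        if self.algorithm == "LDA":
            return LinearDiscriminantAnalysis(**hp)
        raise AssertionError(self.algorithm)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "hyperparams": dict(self.hyperparams),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BaseLearnerSpec":
        return cls(d["algorithm"], dict(d.get("hyperparams", {})), int(d.get("seed", 0)))


def positive_probability(estimator, X: np.ndarray) -> np.ndarray:
    """Positive-class probability from any supported fitted estimator.

    Ridge classification exposes only a signed decision function; it is
    squashed through the logistic function to the unit interval so all
    base learners feed the meta-learner on a common scale.
    """
    if hasattr(estimator, "predict_proba"):
        classes = list(estimator.classes_)
        return estimator.predict_proba(X)[:, classes.index(1)]
    d = estimator.decision_function(X)
    return expit(d if estimator.classes_[1] == 1 else -d)


@dataclass(frozen=True)
class StackingConfig:
    """Base learners, meta learner and out-of-fold split for stacking."""

    base: tuple[BaseLearnerSpec, ...]
    meta: BaseLearnerSpec
    oof_folds: int = 5
    preset_id: str | None = None

    def __post_init__(self) -> None:
        if not self.base:
            raise ValueError("at least one base learner is required")
        if self.oof_folds < 2:
            raise ValueError("oof_folds must be >= 2")
        object.__setattr__(self, "base", tuple(self.base))

    def reseed(self, seed: int) -> "StackingConfig":
        """Derive a copy with all learner seeds re-keyed from ``seed``."""
        base = tuple(
            replace(b, seed=(seed * 1009 + i) % (2**31 - 1))
            for i, b in enumerate(self.base)
        )
        meta = replace(self.meta, seed=(seed * 1009 + len(base)) % (2**31 - 1))
        return StackingConfig(base, meta, self.oof_folds, self.preset_id)

    def to_dict(self) -> dict:
        return {
            "base": [b.to_dict() for b in self.base],
            "meta": self.meta.to_dict(),
            "oof_folds": self.oof_folds,
            "preset_id": self.preset_id,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StackingConfig":
        return cls(
            tuple(BaseLearnerSpec.from_dict(b) for b in d["base"]),
            BaseLearnerSpec.from_dict(d["meta"]),
            int(d.get("oof_folds", 5)),
            d.get("preset_id"),
        )


#: Ensemble compositions evaluated per species; the retained ones are
#: Ensemble3 (Hs), Ensemble1 (Mm) and Ensemble5 (Dm).
ENSEMBLE_PRESETS = {
    "Ensemble1": (("CatBoost", "ET"), "ET"),
    "Ensemble3": (("ET", "RF"), "ET"),
    "Ensemble5": (("ET", "CatBoost", "RF", "LR", "Ridge", "LDA"), "LR"),
}

SPECIES_ENSEMBLE = {"Hs": "Ensemble3", "Mm": "Ensemble1", "Dm": "Ensemble5"}


def species_stacking_preset(species: str, seed: int = 0) -> StackingConfig:
    """Stacking configuration retained for a species (Hs, Mm or Dm)."""
    try:
        preset_id = SPECIES_ENSEMBLE[species]
    except KeyError:
        raise ValueError(
            f"no stacking preset for species {species!r}; known: {sorted(SPECIES_ENSEMBLE)}"
        ) from None
    base_names, meta_name = ENSEMBLE_PRESETS[preset_id]
    cfg = StackingConfig(
        base=tuple(BaseLearnerSpec(a) for a in base_names),
        meta=BaseLearnerSpec(meta_name),
        preset_id=preset_id,
    )
    return cfg.reseed(seed)


@dataclass
class PredictionResult:
    """Per-sample positive-class probability and thresholded label."""

    ids: list[str]
    probability: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probability, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
        self.probability = p

    @property
    def label(self) -> np.ndarray:
        """Hard 0/1 labels; probability >= threshold counts as positive."""
        return (self.probability >= self.threshold).astype(int)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tprobability\tlabel\n")
            for i, p, l in zip(self.ids, self.probability, self.label):
                fh.write(f"{i}\t{p:.6f}\t{'positive' if l else 'negative'}\n")


class StackedModel:
    """A fitted stack: base learners, meta learner and feature schema.

    Use :func:`fit_stacking` to construct; :meth:`predict_proba` /
    :meth:`predict` apply the stack to a matrix whose schema matches the
    training schema exactly (same descriptor names, same order).
    """

    def __init__(self, config, columns, base_models, meta_model, metadata):
        self.config = config
        self.columns = list(columns)
        self.base_models = base_models
        self.meta_model = meta_model
        self.metadata = metadata

    def _check_schema(self, matrix: FeatureMatrix) -> np.ndarray:
        cols = matrix.columns
        if cols != self.columns:
            missing = [c for c in self.columns if c not in set(cols)]
            extra = [c for c in cols if c not in set(self.columns)]
            if missing or extra:
                raise SchemaMismatchError(
                    f"schema mismatch: missing {missing[:5]} "
                    f"({len(missing)} total), unexpected {extra[:5]} ({len(extra)} total)"
                )
            return matrix.data[self.columns].to_numpy(dtype=float)
        return matrix.X

    def meta_features(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [positive_probability(m, X) for m in self.base_models]
        )

    def predict_proba(self, matrix: FeatureMatrix) -> np.ndarray:
        X = self._check_schema(matrix)
        return positive_probability(self.meta_model, self.meta_features(X))

    def predict(self, matrix: FeatureMatrix, threshold: float = 0.5) -> PredictionResult:
        proba = self.predict_proba(matrix)
        return PredictionResult(list(matrix.data.index), proba, threshold)

    def save(self, path: str | Path) -> None:
        """Persist learners + schema + config in one archive."""
        payload = {
            "config": self.config.to_dict(),
            "columns": self.columns,
            "base_models": self.base_models,
            "meta_model": self.meta_model,
            "metadata": self.metadata,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "StackedModel":
        payload = joblib.load(path)
        return cls(
            StackingConfig.from_dict(payload["config"]),
            payload["columns"],
            payload["base_models"],
            payload["meta_model"],
            payload["metadata"],
        )

    def schema_json(self) -> str:
        return json.dumps(
            {"columns": self.columns, "config": self.config.to_dict()}, indent=2
        )


def oof_meta_features(
    X: np.ndarray, y: np.ndarray, config: StackingConfig, seed: int
) -> np.ndarray:
    """Out-of-fold positive-class probabilities of every base learner.

    Stratified ``config.oof_folds``-fold split (shuffled with ``seed``);
    each base learner is fit on the training side of every fold and
    scores only the held-out rows, yielding an (n, n_base) matrix with
    no row scored by a model that saw it.
    """
    skf = StratifiedKFold(n_splits=config.oof_folds, shuffle=True, random_state=seed)
    meta = np.zeros((len(y), len(config.base)))
    for train_idx, test_idx in skf.split(X, y):
        for j, spec in enumerate(config.base):
            model = spec.build()
            model.fit(X[train_idx], y[train_idx])
            meta[test_idx, j] = positive_probability(model, X[test_idx])
    return meta


def fit_stacking(
    matrix: FeatureMatrix,
    labels: np.ndarray | Sequence[int],
    config: StackingConfig,
    seed: int = 0,
) -> StackedModel:
    """Fit a stacked ensemble on a descriptor matrix.

    Meta-features are out-of-fold base probabilities; the meta learner
    is fit on them; base learners are then refit on all rows for
    deployment.  Identical (matrix, labels, config, seed) give
    bit-identical behaviour.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) != len(matrix):
        raise ValueError(f"{len(matrix)} rows but {len(y)} labels")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; need both positives and negatives")
    if counts.min() < config.oof_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < oof_folds={config.oof_folds}"
        )
    X = matrix.X
    if np.isnan(X).any():
        raise ValueError("descriptor matrix contains missing values")
    meta = oof_meta_features(X, y, config, seed)
    meta_model = config.meta.build()
    meta_model.fit(meta, y)
    base_models = []
    for spec in config.base:
        m = spec.build()
        m.fit(X, y)
        base_models.append(m)
    metadata = {
        "seed": seed,
        "oof_folds": config.oof_folds,
        "n_samples": len(y),
        "class_counts": {int(c): int(n) for c, n in zip(classes, counts)},
    }
    return StackedModel(config, matrix.columns, base_models, meta_model, metadata)


def feature_importance(
    spec: BaseLearnerSpec,
    matrix: FeatureMatrix,
    labels: np.ndarray | Sequence[int],
) -> list[tuple[str, float]]:
    """Per-descriptor importance of one base learner, descending.

    Tree learners report impurity-based importances.  Linear learners
    report absolute coefficients fitted on per-column standardized
    descriptors, which puts coefficients on a comparable scale (a
    constant column gets importance exactly 0).  The result is a
    permutation of all columns; ties keep column order (stable sort).
    """
    y = np.asarray(labels, dtype=int)
    X = matrix.X
    model = spec.build()
    if spec.algorithm in TREE_ALGORITHMS:
        model.fit(X, y)
        imp = np.asarray(model.feature_importances_, dtype=float)
    else:
        scaler = StandardScaler()
        Xs = scaler.fit_transform(X)
        model.fit(Xs, y)
        coef = np.asarray(model.coef_, dtype=float).ravel()
        imp = np.abs(coef)
        imp[scaler.var_ == 0.0] = 0.0  # constant columns carry no signal
    order = np.argsort(-imp, kind="stable")
    cols = matrix.columns
    return [(cols[i], float(imp[i])) for i in order]
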