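"""Random Forest training and per-residue linker prediction.

Each training instance is the window-averaged feature vector of one residue;
the positive class is "linker".  Trees are grown on bootstrap samples of the
full training set, drawing m features uniformly at each node and splitting
on Gini impurity, with no depth limit ("grown to purity").  The ensemble
predicts by majority vote; the vote fraction (trees voting linker / total
trees) is exposed so thresholds other than one half can be applied.  No
class weighting or resampling is used: the classifier sees the imbalanced
residue population as-is.

scikit-learn's ``RandomForestClassifier`` provides the ensemble machinery;
the vote fraction is computed from the individual trees' hard votes, not
from averaged leaf probabilities, so it is always a multiple of 1/n_trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .profiles import ResidueProfile
from .sequence_io import SegmentAnnotation, segments_from_labels

_PERSIST_FORMAT = 1


def auto_m_features(n_features: int) -> int:
    """Features drawn per node: floor(log2(M)) + 1."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    return int(math.floor(math.log2(n_features))) + 1


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters of the residue-level Random Forest."""

    n_trees: int = 200
    m_features: int | Literal["auto"] = "auto"
    seed: int = 0
    vote_threshold: float = 0.5
    min_linker_run: int = 0
    bootstrap: bool = True  # disabling is a test-only reduction to bagged-off trees

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if not (0.0 < self.vote_threshold < 1.0):
            raise ValueError("vote_threshold must lie in (0, 1)")
        if self.min_linker_run < 0:
            raise ValueError("min_linker_run must be non-negative")

    def resolve_m(self, n_features: int) -> int:
        m = auto_m_features(n_features) if self.m_features == "auto" else self.m_features
        if not (1 <= m <= n_features):
            raise ValueError(f"m_features {m} not in [1, {n_features}]")
        return m


@dataclass
class ForestModel:
    """A trained ensemble plus the feature contract it was trained under."""

    config: ForestConfig
    estimator: RandomForestClassifier
    feature_names: list[str]
    training_class_priors: tuple[float, float]  # (domain, linker) fractions

    @property
    def n_trees(self) -> int:
        return len(self.estimator.estimators_)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format": _PERSIST_FORMAT,
                "config": self.config,
                "estimator": self.estimator,
                "feature_names": self.feature_names,
                "training_class_priors": self.training_class_priors,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ForestModel":
        payload = joblib.load(path)
        if payload.get("format") != _PERSIST_FORMAT:
            raise ValueError(f"unsupported model file format in {path}")
        return cls(
            config=payload["config"],
            estimator=payload["estimator"],
            feature_names=payload["feature_names"],
            training_class_priors=payload["training_class_priors"],
        )


@dataclass
class PredictionResult:
    """Per-residue votes, thresholded labels, and derived linker segments."""

    seq_id: str
    vote_fraction: np.ndarray
    labels: np.ndarray
    segments: list[SegmentAnnotation] = field(default_factory=list)


def train_forest(
    X: np.ndarray, y: np.ndarray, config: ForestConfig = ForestConfig()
) -> ForestModel:
    """Fit the forest on residue instances ``X`` (N x M) with labels ``y``.

    Deterministic for a fixed seed and input order.  A single-class ``y``
    is allowed (every tree then votes that class).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be 2-D with at least one feature")
    if X.shape[0] < 2:
        raise ValueError("need at least two training instances")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths differ")
    m = config.resolve_m(X.shape[1])
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features=m,
        max_depth=None,
        min_samples_split=2,
        min_samples_leaf=1,
        bootstrap=config.bootstrap,
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(X, y)
    linker_prior = float(np.mean(y == 1))
    return ForestModel(
        config=config,
        estimator=est,
        feature_names=[f"f{i}" for i in range(X.shape[1])],
        training_class_priors=(1.0 - linker_prior, linker_prior),
    )


def vote_fractions(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting linker for each row of ``X``."""
    X = np.asarray(X, dtype=float)
    classes = model.estimator.classes_
    if 1 not in classes:
        return np.zeros(X.shape[0])
    if len(classes) == 1:
        return np.ones(X.shape[0])
    # hard votes per tree; trees share the ensemble's classes_ ordering
    votes = np.zeros(X.shape[0])
    X32 = X.astype(np.float32)
    for tree in model.estimator.estimators_:
        votes += tree.predict(X32)
    return votes / model.n_trees


def filter_min_run(labels: np.ndarray, min_run: int) -> np.ndarray:
    """Zero out runs of 1s shorter than ``min_run`` residues."""
    labels = np.asarray(labels).astype(np.int8).copy()
    if min_run <= 1:
        return labels
    padded = np.concatenate([[0], labels, [0]])
    diff = np.diff(padded)
    for s, e in zip(np.nonzero(diff == 1)[0], np.nonzero(diff == -1)[0]):
        if e - s < min_run:
            labels[s:e] = 0
    return labels


def predict_votes(model: ForestModel, profile: ResidueProfile) -> PredictionResult:
    """Predict per-residue linker votes and segments for one profile."""
    if profile.feature_names != model.feature_names:
        raise ValueError(
            "profile features do not match the model's training features: "
            f"{profile.feature_names} vs {model.feature_names}"
        )
    votes = vote_fractions(model, profile.matrix)
    labels = (votes >= model.config.vote_threshold).astype(np.int8)
    labels = filter_min_run(labels, model.config.min_linker_run)
    return PredictionResult(
        seq_id=profile.seq_id,
        vote_fraction=votes,
        labels=labels,
        segments=segments_from_labels(profile.seq_id, labels),
    )


def train_on_profiles(
    profiles: list[ResidueProfile],
    labels: list[np.ndarray],
    config: ForestConfig = ForestConfig(),
) -> ForestModel:
    """Stack per-sequence profiles into one instance matrix and train."""
    if not profiles:
        raise ValueError("no profiles given")
    X = np.vstack([p.matrix for p in profiles])
    y = np.concatenate([np.asarray(l, dtype=int) for l in labels])
    model = train_forest(X, y, config)
    model.feature_names = list(profiles[0].feature_names)
    return model
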