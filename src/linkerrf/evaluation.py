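"""Residue-level evaluation: metrics, cross-validation, sweeps, ablation.

Linker residues are the positive class.  With TP/TN/FP/FN counted over
residues,

    Ac = (TP + TN) / (TP + TN + FN + FP)
    R  = TP / (TP + FN)          (sensitivity / recall)
    P  = TP / (TP + FP)          (precision)
    F1 = 2 P R / (P + R)

Recall and precision are the informative measures here because the classes
are heavily imbalanced (linkers are a few percent of residues).  Folds are
split at the sequence level: window-averaged features of neighbouring
residues are strongly correlated, so residue-level splits would leak test
information into training and inflate every metric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .forest import ForestConfig, predict_votes, train_on_profiles
from .profiles import (
    EncodingConfig,
    PropertyTables,
    build_profiles,
    compute_linker_index,
)
from .sequence_io import AnnotatedCorpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Residue-level confusion counts, linker = positive."""

    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN,
            self.FP + other.FP, self.FN + other.FN,
        )

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def metrics_from_counts(counts: ConfusionCounts) -> tuple[float, float, float, float, list[str]]:
    """(accuracy, recall, precision, f1, zero-denominator flags)."""
    flags: list[str] = []

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    ac = _ratio(counts.TP + counts.TN, counts.total, "accuracy")
    r = _ratio(counts.TP, counts.TP + counts.FN, "recall")
    p = _ratio(counts.TP, counts.TP + counts.FP, "precision")
    if p + r == 0:
        flags.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * p * r / (p + r)
    return ac, r, p, f1, flags


def f_measure(recall: float, precision: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    """Confusion counts and the four residue-level metrics.

    ``aggregation`` records whether the headline metrics are computed from
    the pooled counts or are unweighted means over cross-validation folds
    (in which case ``counts`` still holds the pooled sums and ``per_fold``
    the individual fold reports).
    """

    counts: ConfusionCounts
    accuracy: float
    recall: float
    precision: float
    f1: float
    aggregation: str = "pooled"
    zero_division_flags: list[str] = field(default_factory=list)
    per_fold: list["EvalReport"] | None = None

    @classmethod
    def from_counts(cls, counts: ConfusionCounts) -> "EvalReport":
        ac, r, p, f1, flags = metrics_from_counts(counts)
        return cls(counts, ac, r, p, f1, zero_division_flags=flags)

    def pooled_metrics(self) -> "EvalReport":
        """Metrics recomputed from the pooled counts."""
        return EvalReport.from_counts(self.counts)


def score(
    truth: Sequence[np.ndarray], predicted: Sequence[np.ndarray]
) -> EvalReport:
    """Pool residue-level confusion counts over aligned label vectors."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted have different numbers of sequences")
    counts = ConfusionCounts()
    for t, p in zip(truth, predicted):
        t = np.asarray(t, dtype=bool)
        p = np.asarray(p, dtype=bool)
        if t.shape != p.shape:
            raise ValueError("label vector length mismatch")
        counts = counts + ConfusionCounts(
            TP=int(np.count_nonzero(t & p)),
            TN=int(np.count_nonzero(~t & ~p)),
            FP=int(np.count_nonzero(~t & p)),
            FN=int(np.count_nonzero(t & ~p)),
        )
    return EvalReport.from_counts(counts)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the profile -> forest pipeline.

    ``pseudocount`` regularizes per-fold linker-index estimation: rare
    amino acids can be absent from the linker partition of a small training
    fold, and the raw log-ratio would be infinite there.
    """

    encoding: EncodingConfig = EncodingConfig()
    forest: ForestConfig = ForestConfig()
    window: int = 41
    pseudocount: float = 0.01
    tables: PropertyTables | None = None

    def resolved_tables(self) -> PropertyTables:
        return self.tables if self.tables is not None else PropertyTables.default()


def _fit_and_score_split(
    corpus: AnnotatedCorpus,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    pipeline: PipelineConfig,
    column_mask: np.ndarray | None,
    fold_seed: int,
) -> ConfusionCounts:
    tables = pipeline.resolved_tables()
    train_seqs = [corpus.sequences[i] for i in train_idx]
    train_labels = [corpus.labels[i] for i in train_idx]
    if pipeline.encoding.linker_index_source == "estimated_from_training":
        index, lf, df = compute_linker_index(
            AnnotatedCorpus(train_seqs, train_labels), pipeline.pseudocount
        )
        tables = tables.with_linker_index(index, lf, df)
    train_profiles = build_profiles(
        train_seqs, tables, pipeline.encoding, pipeline.window
    )
    test_profiles = build_profiles(
        [corpus.sequences[i] for i in test_idx], tables,
        pipeline.encoding, pipeline.window,
    )
    if column_mask is not None:
        for prof in (*train_profiles, *test_profiles):
            prof.matrix = prof.matrix[:, column_mask]
            prof.feature_names = [
                n for n, keep in zip(prof.feature_names, column_mask) if keep
            ]
    forest_cfg = replace(pipeline.forest, seed=fold_seed)
    model = train_on_profiles(train_profiles, train_labels, forest_cfg)
    model.feature_names = list(train_profiles[0].feature_names)
    truth = [corpus.labels[i] for i in test_idx]
    predicted = [predict_votes(model, prof).labels for prof in test_profiles]
    return score(truth, predicted).counts


def cross_validate(
    corpus: AnnotatedCorpus,
    k: int = 10,
    pipeline: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    column_mask: np.ndarray | None = None,
) -> EvalReport:
    """Sequence-level k-fold cross-validation of the full pipeline.

    Per fold the linker index is re-estimated on the training sequences
    (when the encoding says so), profiles are built, a forest is trained,
    and the held-out sequences are scored.  The returned report carries
    fold-mean metrics as the headline numbers, pooled counts, and the
    per-fold reports; ``k`` equal to the number of sequences gives
    leave-one-sequence-out.
    """
    n = len(corpus)
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}], got {k}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports: list[EvalReport] = []
    pooled = ConfusionCounts()
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.arange(n))):
        counts = _fit_and_score_split(
            corpus, train_idx, test_idx, pipeline, column_mask,
            fold_seed=(seed * 1000 + fold) % (2**31 - 1),
        )
        fold_reports.append(EvalReport.from_counts(counts))
        pooled = pooled + counts
    mean = lambda attr: float(np.mean([getattr(r, attr) for r in fold_reports]))
    r_mean, p_mean = mean("recall"), mean("precision")
    return EvalReport(
        counts=pooled,
        accuracy=mean("accuracy"),
        recall=r_mean,
        precision=p_mean,
        f1=mean("f1"),
        aggregation="fold_mean",
        per_fold=fold_reports,
    )


def _subset(corpus: AnnotatedCorpus, size: int, rng: np.random.Generator) -> AnnotatedCorpus:
    if size > len(corpus):
        raise ValueError("subset_size exceeds corpus size")
    idx = np.sort(rng.choice(len(corpus), size=size, replace=False))
    return AnnotatedCorpus(
        [corpus.sequences[i] for i in idx], [corpus.labels[i] for i in idx]
    )


def sweep_window(
    corpus: AnnotatedCorpus,
    sizes: Iterable[int] = range(7, 46, 2),
    subset_size: int = 50,
    pipeline: PipelineConfig = PipelineConfig(),
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate at each odd window size on one random sequence subset."""
    sizes = list(sizes)
    for w in sizes:
        if w < 1 or w % 2 == 0:
            raise ValueError(f"window sizes must be odd and positive, got {w}")
    sub = _subset(corpus, subset_size, np.random.default_rng(seed))
    rows = []
    for w in sizes:
        rep = cross_validate(sub, k, replace(pipeline, window=w), seed)
        rows.append(
            {"window": w, "recall": rep.recall, "precision": rep.precision,
             "f1": rep.f1}
        )
    return pd.DataFrame(rows)


def sweep_trees(
    corpus: AnnotatedCorpus,
    tree_counts: Iterable[int] = (10, 25, 50, 100, 200, 300, 400, 500),
    subset_size: int = 50,
    pipeline: PipelineConfig = PipelineConfig(),
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate at each forest size on one random sequence subset."""
    tree_counts = list(tree_counts)
    if len(set(tree_counts)) != len(tree_counts):
        raise ValueError("duplicate tree counts")
    for t in tree_counts:
        if t < 1:
            raise ValueError(f"tree count must be positive, got {t}")
    sub = _subset(corpus, subset_size, np.random.default_rng(seed))
    rows = []
    for t in tree_counts:
        cfg = replace(pipeline, forest=replace(pipeline.forest, n_trees=t))
        rep = cross_validate(sub, k, cfg, seed)
        rows.append(
            {"n_trees": t, "recall": rep.recall, "precision": rep.precision,
             "f1": rep.f1}
        )
    return pd.DataFrame(rows)


def _entropy_bits(pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binary entropy (bits) of ``pos`` positives among ``n``, elementwise."""
    pos = np.asarray(pos, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, pos / np.maximum(n, 1), 0.0)
        h = -(p * np.log2(np.maximum(p, 1e-300))
              + (1 - p) * np.log2(np.maximum(1 - p, 1e-300)))
    h[(p <= 0) | (p >= 1)] = 0.0
    return h


def information_gain(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Best-binary-threshold information gain of each column, in bits.

    For a continuous feature the gain is H(y) minus the minimum, over all
    thresholds t between adjacent distinct values, of the size-weighted
    entropy of y split into X <= t and X > t (the C4.5-style criterion used
    to rank features in decision-tree practice).  Invariant under strictly
    monotone feature transformations.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 2:
        raise ValueError("need at least two instances")
    h_y = float(_entropy_bits(np.array([np.sum(y == 1)]), np.array([n]))[0])
    if h_y == 0.0:
        warnings.warn("labels are constant; every information gain is 0")
        return np.zeros(X.shape[1])
    gains = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        xj = X[:, j]
        order = np.argsort(xj, kind="stable")
        xs, ys = xj[order], y[order]
        cum_pos = np.cumsum(ys == 1)
        # candidate split after position i (1-based sizes), only between
        # distinct feature values
        valid = np.nonzero(np.diff(xs) > 0)[0]
        if valid.size == 0:
            continue
        n_left = valid + 1
        pos_left = cum_pos[valid]
        n_right = n - n_left
        pos_right = cum_pos[-1] - pos_left
        h_split = (
            n_left * _entropy_bits(pos_left, n_left)
            + n_right * _entropy_bits(pos_right, n_right)
        ) / n
        gains[j] = max(0.0, h_y - float(np.min(h_split)))
    return gains


def group_information_gain(
    X: np.ndarray, y: np.ndarray, groups: dict[str, list[int]]
) -> dict[str, float]:
    """Mean column IG per feature group."""
    ig = information_gain(X, y)
    return {name: float(np.mean(ig[cols])) for name, cols in groups.items()}


def ablate_by_ig(
    corpus: AnnotatedCorpus,
    pipeline: PipelineConfig = PipelineConfig(),
    k: int = 10,
    seed: int = 0,
    cumulative: bool = True,
) -> pd.DataFrame:
    """Feature-group ablation ordered by ascending information gain.

    The profile matrix of the whole corpus is built once to rank the seven
    property groups by mean column IG.  Row 0 evaluates the full feature
    set; subsequent rows re-run the cross-validation after removing groups
    (cumulatively in ascending-IG order by default, or one group at a time
    with ``cumulative=False``).  Ablation stops before the feature set
    would become empty.
    """
    tables = pipeline.resolved_tables()
    if pipeline.encoding.linker_index_source == "estimated_from_training":
        index, lf, df = compute_linker_index(corpus, pipeline.pseudocount)
        tables = tables.with_linker_index(index, lf, df)
    profiles = build_profiles(
        corpus.sequences, tables, pipeline.encoding, pipeline.window
    )
    X = np.vstack([p.matrix for p in profiles])
    y = np.concatenate([np.asarray(l, dtype=int) for l in corpus.labels])
    groups = pipeline.encoding.feature_groups()
    group_ig = group_information_gain(X, y, groups)
    order = sorted(groups, key=lambda g: group_ig[g])  # ascending IG

    n_cols = X.shape[1]
    rows = []
    full = cross_validate(corpus, k, pipeline, seed)
    rows.append(
        {"removed": "none", "group_ig": np.nan, "recall": full.recall,
         "precision": full.precision, "f1": full.f1}
    )
    mask = np.ones(n_cols, dtype=bool)
    for i, name in enumerate(order):
        if cumulative:
            mask[groups[name]] = False
            removed = " + ".join(order[: i + 1])
            current = mask
        else:
            current = np.ones(n_cols, dtype=bool)
            current[groups[name]] = False
            removed = name
        if not current.any():
            break  # never evaluate an empty feature set
        rep = cross_validate(corpus, k, pipeline, seed, column_mask=current)
        rows.append(
            {"removed": removed, "group_ig": group_ig[name], "recall": rep.recall,
             "precision": rep.precision, "f1": rep.f1}
        )
    return pd.DataFrame(rows)
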