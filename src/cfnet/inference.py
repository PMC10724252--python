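"""Supervised interactome inference from CF-MS co-elution features.

A random-forest classifier is trained on complex-derived labeled pairs in
complex-level cross-validation and scores every protein pair, yielding a
ranked interaction list with cumulative precision that can be thresholded at
a target precision (default 50%) or at a fixed top-k. Two strategies extend
the paradigm to training-data-poor species:

* *data augmentation* — labeled feature rows from external CF-MS experiments
  are injected into the training set (and discarded afterwards, so they never
  influence the ranked list or its precision);
* *cross-species transfer* — the classifier is trained entirely on external
  labeled pairs grouped into pseudo-replicates matching the target species'
  replicate count, then scores the target pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from ._rng import derive_rng, derive_seed
from .errors import ConfigError
from .goldstandard import split_folds
from .similarity import OPTIMAL_MEASURE_ORDER, MeasureSpec, measure_spec, pairwise_features
from .types import EdgeList, ElutionMatrix, LabeledPairSet, Pair

logger = logging.getLogger("cfnet.inference")

__all__ = [
    "tiered_measures",
    "build_feature_table",
    "RankedNetwork",
    "train_score_cv",
    "precision_curve",
    "roc_auc",
    "threshold_network",
    "threshold_topk",
    "ExternalFeaturePool",
    "AugmentedTraining",
    "augment_training",
    "TransferModel",
    "transfer_train",
    "transfer_score",
]


def tiered_measures(n_experiments: int) -> list[MeasureSpec]:
    """Measures per experiment under the feature-tier rule.

    More experiments need fewer measures each: >10 experiments -> a single
    feature per experiment (distance correlation); 6-10 -> two (adding
    weighted cross-correlation); <=5 -> four (adding cosine similarity and
    mutual information), in descending benchmark-performance order.
    """
    if n_experiments < 1:
        raise ValueError("need >= 1 experiment")
    if n_experiments > 10:
        names = OPTIMAL_MEASURE_ORDER[:1]
    elif n_experiments >= 6:
        names = OPTIMAL_MEASURE_ORDER[:2]
    else:
        names = OPTIMAL_MEASURE_ORDER[:4]
    return [measure_spec(m) for m in names]


def build_feature_table(
    experiments: Sequence[ElutionMatrix],
    seed: int = 0,
    specs: Optional[Sequence[MeasureSpec]] = None,
) -> pd.DataFrame:
    """Assemble the pair x (experiment, measure) feature table for one species.

    The pair universe is the union over experiments of co-detected pairs;
    a pair lacking either protein in an experiment carries the NaN
    missing-feature marker in that experiment's columns. Columns are a
    two-level (experiment_id, measure) MultiIndex.
    """
    if specs is None:
        specs = tiered_measures(len(experiments))
    blocks = []
    for exp in experiments:
        feats = pairwise_features(exp, specs, seed=seed)
        feats.columns = pd.MultiIndex.from_product(
            [[exp.experiment_id], feats.columns], names=["experiment", "measure"]
        )
        blocks.append(feats)
    table = pd.concat(blocks, axis=1)
    table = table.sort_index()
    return table


# ---------------------------------------------------------------------------
# Ranked networks, precision, AUROC
# ---------------------------------------------------------------------------


@dataclass
class RankedNetwork:
    """Pairs ordered by classifier score with cumulative precision.

    ``labels[i]`` is 1/0 for labeled pairs and NaN for unlabeled ones;
    ``precision[i]`` is the cumulative precision over labeled pairs within
    the top i+1 ranks (NaN until the first labeled pair is encountered).
    """

    pairs: list[Pair]
    scores: np.ndarray
    labels: np.ndarray
    precision: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.pairs)

    def auroc(self) -> float:
        """Mann-Whitney AUROC of the scores over the labeled pairs."""
        labeled = ~np.isnan(self.labels)
        return roc_auc(self.scores[labeled], self.labels[labeled])

    def to_edge_list(self, k: Optional[int] = None) -> EdgeList:
        k = len(self.pairs) if k is None else k
        pairs = self.pairs[:k]
        return EdgeList(edges=pairs, scores={p: float(s) for p, s in zip(pairs, self.scores[:k])})


def precision_curve(labels: Sequence[float]) -> np.ndarray:
    """Cumulative precision along a ranked list.

    ``labels`` follows the ranking order with 1 (true positive), 0 (false
    positive) or NaN (unlabeled; does not change the running value). Before
    the first labeled pair the precision is undefined (NaN).
    """
    lab = np.asarray(labels, dtype=float)
    tp = np.cumsum(np.nan_to_num(lab == 1, nan=0.0))
    n_labeled = np.cumsum(~np.isnan(lab))
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(n_labeled > 0, tp / np.maximum(n_labeled, 1), np.nan)
    return prec


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exact rank-based (Mann-Whitney) AUROC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels == 1
    neg = labels == 0
    n_pos = int(pos.sum())
    n_neg = int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores[pos | neg])
    return float((ranks[pos[pos | neg]].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def threshold_network(ranked: RankedNetwork, target_precision: float = 0.5) -> EdgeList:
    """Truncate a ranked list at the deepest rank meeting a precision target.

    Retains the top ``k`` ranks, where ``k`` is the largest rank whose
    cumulative precision over labeled pairs is >= ``target_precision``;
    returns an empty network if the target is never reached.
    """
    if not 0.0 < target_precision <= 1.0:
        raise ConfigError("target precision must lie in (0, 1]")
    meets = np.nonzero(ranked.precision >= target_precision)[0]
    if meets.size == 0:
        logger.info("precision target %.2f never reached; empty network", target_precision)
        return EdgeList(edges=[], scores={})
    return ranked.to_edge_list(k=int(meets[-1]) + 1)


def threshold_topk(ranked: RankedNetwork, k: int) -> EdgeList:
    """Retain the first ``k`` pairs (ties already broken deterministically)."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > len(ranked):
        logger.warning("k=%d exceeds list length %d; returning whole list", k, len(ranked))
        k = len(ranked)
    return ranked.to_edge_list(k=k)


# ---------------------------------------------------------------------------
# Cross-validated training and scoring
# ---------------------------------------------------------------------------


def _rank_order(pairs: list[Pair], scores: np.ndarray) -> np.ndarray:
    """Descending score; ties broken by alphabetized pair order."""
    order = sorted(range(len(pairs)), key=lambda i: (-scores[i], pairs[i]))
    return np.asarray(order, dtype=int)


def _fill_missing(X: np.ndarray, how: str) -> np.ndarray:
    if how == "zero":
        return np.nan_to_num(X, nan=0.0)
    if how == "median":
        med = np.nanmedian(X, axis=0)
        med = np.nan_to_num(med, nan=0.0)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = med[idx[1]]
        return X
    raise ConfigError(f"unknown missing_fill strategy: {how!r}")


def train_score_cv(
    features: pd.DataFrame,
    labels: LabeledPairSet,
    k: int = 5,
    n_trees: int = 100,
    seed: int = 0,
    extra_training: Optional["AugmentedTraining"] = None,
    missing_fill: str = "zero",
) -> RankedNetwork:
    """Train per-fold random forests and score every pair in the table.

    Labeled pairs are scored by the model of the fold they were assigned to
    (trained on the other folds); unlabeled pairs are scored by the average
    over the fold models. ``extra_training`` rows (injected external labeled
    pairs) are added to every fold's training set and never scored. Missing
    features are zero-filled immediately before fitting (``missing_fill=
    "median"`` fills with the column median instead).
    """
    folds = split_folds(labels, k=k, seed=seed)
    pair_index = list(features.index)
    pair_pos = {p: i for i, p in enumerate(pair_index)}
    X = _fill_missing(features.to_numpy(dtype=float), missing_fill)
    assert not np.isnan(X).any(), "missing-feature markers must not reach the learner"

    labeled_pairs = [p for p in pair_index if p in labels.labels]
    labeled_idx = np.array([pair_pos[p] for p in labeled_pairs], dtype=int)
    y = np.array([labels.labels[p] for p in labeled_pairs], dtype=int)
    pair_fold = np.array([folds[p] for p in labeled_pairs], dtype=int)

    extra_X = None
    extra_y = None
    if extra_training is not None:
        overlap = set(extra_training.features.index) & set(pair_index)
        if overlap:
            raise ConfigError(f"injected pairs collide with target pairs: {sorted(overlap)[:3]}")
        extra_X = np.nan_to_num(
            extra_training.features.reindex(columns=features.columns).to_numpy(dtype=float),
            nan=0.0,
        )
        extra_y = np.array(
            [extra_training.labels[p] for p in extra_training.features.index], dtype=int
        )

    scores = np.zeros(len(pair_index), dtype=float)
    unlabeled_mask = np.ones(len(pair_index), dtype=bool)
    unlabeled_mask[labeled_idx] = False
    fold_meta = []
    models = []
    for f in range(k):
        train_mask = pair_fold != f
        X_train = X[labeled_idx[train_mask]]
        y_train = y[train_mask]
        if extra_X is not None and len(extra_X):
            X_train = np.vstack([X_train, extra_X])
            y_train = np.concatenate([y_train, extra_y])
        if len(np.unique(y_train)) < 2:
            raise ConfigError(
                f"training fold {f} contains a single class; use fewer folds or more labels"
            )
        model = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=derive_seed(seed, "forest", f),
            n_jobs=1,
        )
        model.fit(X_train, y_train)
        models.append(model)
        test_idx = labeled_idx[pair_fold == f]
        if test_idx.size:
            scores[test_idx] = model.predict_proba(X[test_idx])[:, 1]
        fold_meta.append(
            {"fold": f, "n_train": int(len(y_train)), "n_test": int(test_idx.size)}
        )

    if unlabeled_mask.any():
        proba = np.zeros(int(unlabeled_mask.sum()))
        for model in models:
            proba += model.predict_proba(X[unlabeled_mask])[:, 1]
        scores[unlabeled_mask] = proba / len(models)

    order = _rank_order(pair_index, scores)
    ranked_pairs = [pair_index[i] for i in order]
    ranked_scores = scores[order]
    ranked_labels = np.array(
        [labels.labels.get(p, np.nan) for p in ranked_pairs], dtype=float
    )
    metadata = {
        "k_folds": k,
        "n_trees": n_trees,
        "seed": seed,
        "folds": fold_meta,
        "hyperparameters": models[0].get_params() if models else {},
        "augmented": extra_training.audit if extra_training is not None else None,
    }
    return RankedNetwork(
        pairs=ranked_pairs,
        scores=ranked_scores,
        labels=ranked_labels,
        precision=precision_curve(ranked_labels),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Data augmentation with external labeled pairs
# ---------------------------------------------------------------------------


@dataclass
class ExternalFeaturePool:
    """Labeled feature rows from external CF-MS experiments.

    ``experiments`` maps external experiment id -> DataFrame indexed by
    alphabetized pair tuples with one column per measure (default pools carry
    distance correlation only); ``labels`` maps pair -> 1/0.
    """

    experiments: dict[str, pd.DataFrame]
    labels: dict[Pair, int]

    @property
    def pairs(self) -> list[Pair]:
        out: set[Pair] = set()
        for df in self.experiments.values():
            out.update(df.index)
        return sorted(out & set(self.labels))


@dataclass
class AugmentedTraining:
    """Injected external rows aligned to the target feature columns."""

    features: pd.DataFrame
    labels: dict[Pair, int]
    audit: dict = field(default_factory=dict)


def augment_training(
    features: pd.DataFrame,
    labels: LabeledPairSet,
    pool: ExternalFeaturePool,
    proportion: float = 0.33,
    seed: int = 0,
) -> AugmentedTraining:
    """Sample external labeled pairs and align them to target feature columns.

    ``floor(proportion * n_target_labeled)`` external labeled pairs are drawn
    without replacement; each external experiment is mapped uniformly at
    random onto a target experiment column, and an injected pair's row takes
    its features from the external experiments mapped to each column.
    Injected identifiers are namespaced so they can never collide with (or
    leak into) the scored target pairs.
    """
    if proportion < 0:
        raise ConfigError("proportion must be >= 0")
    n_target_labeled = sum(1 for p in features.index if p in labels.labels)
    n_inject = math.floor(proportion * n_target_labeled)
    candidates = pool.pairs
    if n_inject > len(candidates):
        raise ConfigError(
            f"pool has {len(candidates)} labeled pairs; cannot inject {n_inject}"
        )
    rng = derive_rng(seed, "augmentation")
    chosen_idx = rng.choice(len(candidates), size=n_inject, replace=False)
    chosen = [candidates[i] for i in sorted(chosen_idx)]

    target_exps = list(features.columns.get_level_values("experiment").unique())
    ext_exps = sorted(pool.experiments)
    exp_map = {e: target_exps[int(i)] for e, i in zip(ext_exps, rng.integers(0, len(target_exps), size=len(ext_exps)))}

    rows = []
    filled = 0
    requested = 0
    for pair in chosen:
        row = {}
        ext_order = list(rng.permutation(len(ext_exps)))
        for col in features.columns:
            texp, measure = col
            requested += 1
            value = np.nan
            for j in ext_order:
                e = ext_exps[j]
                if exp_map[e] != texp:
                    continue
                df = pool.experiments[e]
                if pair in df.index and measure in df.columns:
                    v = df.at[pair, measure]
                    if not np.isnan(v):
                        value = float(v)
                        break
            if not np.isnan(value):
                filled += 1
            row[col] = value
        rows.append(row)

    injected_index = pd.Index(
        [(f"EXT::{a}", f"EXT::{b}") for a, b in chosen], tupleize_cols=False
    )
    injected = pd.DataFrame(rows, index=injected_index, columns=features.columns, dtype=float)
    injected_labels = {
        (f"EXT::{a}", f"EXT::{b}"): pool.labels[(a, b)] for a, b in chosen
    }
    audit = {
        "proportion": proportion,
        "n_target_labeled": n_target_labeled,
        "n_injected": n_inject,
        "experiment_map": exp_map,
        "cells_filled": filled,
        "cells_requested": requested,
        "seed": seed,
    }
    logger.info(
        "augmentation: injected %d external pairs (%.0f%% of %d target labeled pairs)",
        n_inject,
        100 * proportion,
        n_target_labeled,
    )
    return AugmentedTraining(features=injected, labels=injected_labels, audit=audit)


# ---------------------------------------------------------------------------
# Cross-species transfer
# ---------------------------------------------------------------------------


@dataclass
class TransferModel:
    """A forest trained on external pseudo-replicate feature vectors."""

    model: RandomForestClassifier
    measures: list[str]
    n_replicates: int
    audit: dict = field(default_factory=dict)


def transfer_train(
    pool: ExternalFeaturePool,
    target_replicate_count: int,
    n_trees: int = 100,
    seed: int = 0,
    measures: Optional[Sequence[str]] = None,
) -> TransferModel:
    """Train a classifier on external labeled pairs grouped into pseudo-replicates.

    Every external labeled pair is assigned (seeded, uniform) a tuple of
    ``target_replicate_count`` external experiments that supply its feature
    vector, matching the replicate count of the target species. If fewer
    external experiments than replicates are available, sampling falls back
    to with-replacement with a warning.
    """
    if target_replicate_count < 1:
        raise ConfigError("target_replicate_count must be >= 1")
    ext_exps = sorted(pool.experiments)
    if measures is None:
        measures = sorted({m for df in pool.experiments.values() for m in df.columns})
    measures = list(measures)
    rng = derive_rng(seed, "transfer")
    replace = len(ext_exps) < target_replicate_count
    if replace:
        logger.warning(
            "only %d external experiments for %d replicates; sampling with replacement",
            len(ext_exps),
            target_replicate_count,
        )
    X_rows = []
    y_rows = []
    for pair in pool.pairs:
        picks = rng.choice(len(ext_exps), size=target_replicate_count, replace=replace)
        vec = []
        for j in picks:
            df = pool.experiments[ext_exps[int(j)]]
            for m in measures:
                v = df.at[pair, m] if (pair in df.index and m in df.columns) else np.nan
                vec.append(0.0 if np.isnan(v) else float(v))
        X_rows.append(vec)
        y_rows.append(pool.labels[pair])
    y = np.asarray(y_rows, dtype=int)
    if len(np.unique(y)) < 2:
        raise ConfigError("external pool must contain both classes")
    model = RandomForestClassifier(
        n_estimators=n_trees, random_state=derive_seed(seed, "transfer_forest"), n_jobs=1
    )
    model.fit(np.asarray(X_rows, dtype=float), y)
    audit = {
        "n_external_experiments": len(ext_exps),
        "n_training_pairs": len(y_rows),
        "n_replicates": target_replicate_count,
        "measures": measures,
        "with_replacement": replace,
        "seed": seed,
    }
    return TransferModel(
        model=model, measures=measures, n_replicates=target_replicate_count, audit=audit
    )


def transfer_score(
    transfer_model: TransferModel,
    features: pd.DataFrame,
    labels: Optional[LabeledPairSet] = None,
) -> RankedNetwork:
    """Score target pairs with a transfer-trained classifier."""
    target_exps = list(features.columns.get_level_values("experiment").unique())
    if len(target_exps) != transfer_model.n_replicates:
        raise ConfigError(
            f"target has {len(target_exps)} experiments but the model was trained "
            f"for {transfer_model.n_replicates} replicates"
        )
    cols = [(e, m) for e in target_exps for m in transfer_model.measures]
    missing_cols = [c for c in cols if c not in features.columns]
    if missing_cols:
        raise ConfigError(f"target feature table lacks columns: {missing_cols[:4]}")
    X = np.nan_to_num(features.loc[:, cols].to_numpy(dtype=float), nan=0.0)
    scores = transfer_model.model.predict_proba(X)[:, 1]
    pair_index = list(features.index)
    order = _rank_order(pair_index, scores)
    ranked_pairs = [pair_index[i] for i in order]
    ranked_scores = scores[order]
    label_map = labels.labels if labels is not None else {}
    ranked_labels = np.array([label_map.get(p, np.nan) for p in ranked_pairs], dtype=float)
    return RankedNetwork(
        pairs=ranked_pairs,
        scores=ranked_scores,
        labels=ranked_labels,
        precision=precision_curve(ranked_labels),
        metadata={"transfer": transfer_model.audit},
    )
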