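"""Network-level evaluation.

* Jaccard overlap between interactome screens.
* Neighbor-voting functional coherence ("guilt by association"): the AUC of
  predicting withheld term annotations from the proportion of a protein's
  network neighbors carrying the term, in three-fold cross-validation.
* Disease-gene connectivity: the same machinery with disease gene sets.
* Coexpression / colocalization of interacting pairs: per-edge Pearson
  correlation across a user-supplied condition-profile matrix.
* Saturation analysis: cumulative proteome coverage as experiments accrue,
  with a logarithmic fit for projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .inference import roc_auc
from .similarity import pearson
from .types import AnnotationSet, EdgeList, ElutionMatrix

logger = logging.getLogger("cfnet.net_eval")

__all__ = [
    "jaccard",
    "CoherenceResult",
    "neighbor_voting_auc",
    "disease_connectivity",
    "pair_property_correlation",
    "saturation_curve",
    "SaturationResult",
]


def jaccard(a: EdgeList, b: EdgeList) -> float:
    """Jaccard index of two alphabetized edge sets (0 if the union is empty)."""
    sa = a.edge_set
    sb = b.edge_set
    union = sa | sb
    if not union:
        logger.info("both networks empty; Jaccard defined as 0")
        return 0.0
    return len(sa & sb) / len(union)


@dataclass
class CoherenceResult:
    """Per-term cross-validated neighbor-voting AUCs with summary statistics."""

    term_auc: dict[str, float]
    term_size: dict[str, int]
    median_auc: float
    fraction_below_half: float
    n_terms_skipped: int = 0
    details: dict = field(default_factory=dict)


def _neighbor_voting(
    network: EdgeList,
    annotations: AnnotationSet,
    folds: int,
    min_size: int | None,
    max_size: int | None,
    seed: int,
) -> CoherenceResult:
    if len(network) == 0:
        raise ValueError("network is empty")
    adj = network.neighbors()
    proteins = sorted(adj)
    degree = {p: len(adj[p]) for p in proteins}

    term_auc: dict[str, float] = {}
    term_size: dict[str, int] = {}
    skipped = 0
    for term in sorted(annotations.terms):
        members = annotations.terms[term]
        if min_size is not None and len(members) < min_size:
            continue
        if max_size is not None and len(members) > max_size:
            continue
        annotated_in_net = sorted(members & set(proteins))
        if len(annotated_in_net) < 2:
            skipped += 1
            logger.info("term %r: <2 annotated proteins in network; skipped", term)
            continue
        rng = derive_rng(seed, "neighbor_voting", term)
        order = rng.permutation(len(annotated_in_net))
        fold_of = {annotated_in_net[i]: int(order[i] % folds) for i in range(len(annotated_in_net))}
        negatives = [p for p in proteins if p not in members]
        aucs = []
        for f in range(folds):
            hidden = {p for p, ff in fold_of.items() if ff == f}
            if not hidden or not negatives:
                continue
            visible = set(annotated_in_net) - hidden
            # Score = fraction of neighbors annotated among the non-hidden;
            # degree-zero cannot occur (every node has an edge), hidden-only
            # neighborhoods score 0 so the ROC stays well-defined.
            def score(p: str) -> float:
                return len(adj[p] & visible) / degree[p]

            pos_scores = [score(p) for p in sorted(hidden)]
            neg_scores = [score(p) for p in negatives]
            auc = roc_auc(
                np.array(pos_scores + neg_scores),
                np.array([1] * len(pos_scores) + [0] * len(neg_scores)),
            )
            if not np.isnan(auc):
                aucs.append(auc)
        if not aucs:
            skipped += 1
            continue
        term_auc[term] = float(np.mean(aucs))
        term_size[term] = len(annotated_in_net)

    if term_auc:
        values = np.array(list(term_auc.values()))
        median = float(np.median(values))
        below = float(np.mean(values < 0.5))
    else:
        median = float("nan")
        below = float("nan")
    return CoherenceResult(
        term_auc=term_auc,
        term_size=term_size,
        median_auc=median,
        fraction_below_half=below,
        n_terms_skipped=skipped,
        details={"folds": folds, "min_size": min_size, "max_size": max_size, "seed": seed},
    )


def neighbor_voting_auc(
    network: EdgeList,
    annotations: AnnotationSet,
    folds: int = 3,
    min_size: int = 10,
    max_size: int = 100,
    seed: int = 0,
) -> CoherenceResult:
    """Functional coherence of a network by cross-validated neighbor voting.

    Terms annotated to fewer than ``min_size`` or more than ``max_size``
    proteins are excluded (defaults 10 and 100). For each retained term the
    annotated proteins are split into ``folds`` seeded folds; per fold, the
    fold members' labels are hidden and every network protein is scored by
    the proportion of its neighbors annotated among the non-hidden. The term
    AUC (hidden positives vs never-annotated proteins, exact rank-based
    Mann-Whitney) is averaged over folds.
    """
    return _neighbor_voting(network, annotations, folds, min_size, max_size, seed)


def disease_connectivity(
    network: EdgeList,
    disease_annotations: AnnotationSet,
    folds: int = 3,
    seed: int = 0,
) -> CoherenceResult:
    """Connectivity of same-disease genes: neighbor voting over disease gene
    sets, without a term-size filter."""
    return _neighbor_voting(network, disease_annotations, folds, None, None, seed)


def pair_property_correlation(
    network: EdgeList,
    profiles: pd.DataFrame,
    min_shared: int = 3,
) -> dict:
    """Per-edge Pearson correlation across a protein x condition matrix.

    Used for coexpression (proteomic profiles) and colocalization
    (subcellular profiles) of interacting pairs. Correlations are computed
    pairwise-complete; edges with fewer than ``min_shared`` shared conditions
    or with a protein absent from the matrix are skipped and counted.
    """
    correlations: dict[tuple[str, str], float] = {}
    skipped_absent = 0
    skipped_overlap = 0
    index = set(profiles.index)
    for a, b in network.edges:
        if a not in index or b not in index:
            skipped_absent += 1
            continue
        x = profiles.loc[a].to_numpy(dtype=float)
        y = profiles.loc[b].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if int(ok.sum()) < min_shared:
            skipped_overlap += 1
            continue
        r = pearson(x, y)
        if np.isnan(r):
            skipped_overlap += 1
            continue
        correlations[(a, b)] = r
    values = np.array(list(correlations.values()))
    return {
        "correlations": correlations,
        "median": float(np.median(values)) if values.size else float("nan"),
        "fraction_negative": float(np.mean(values < 0)) if values.size else float("nan"),
        "n_edges_scored": len(correlations),
        "n_skipped_absent": skipped_absent,
        "n_skipped_overlap": skipped_overlap,
    }


@dataclass
class SaturationResult:
    """Cumulative detected-protein counts and the fitted logarithmic curve."""

    counts: np.ndarray  # shape (repeats, n_experiments)
    a: float
    b: float

    def projection(self, n: float) -> float:
        """Projected protein count after ``n`` experiments: a + b*ln(n)."""
        return float(self.a + self.b * np.log(n))


def saturation_curve(
    experiments: Sequence[ElutionMatrix],
    repeats: int = 10,
    seed: int = 0,
) -> SaturationResult:
    """Proteome-coverage saturation as experiments accumulate.

    Experiments are sampled in random order (``repeats`` seeded shuffles);
    at each step the cumulative number of proteins detected in at least one
    fraction is recorded. A logarithmic curve ``count = a + b*ln(step)`` is
    fit by least squares over all repeats for projecting coverage at larger
    experiment counts.
    """
    if len(experiments) < 2:
        raise ValueError("need >= 2 experiments for a saturation analysis")
    detected_sets = []
    for exp in experiments:
        mask = exp.detected_counts() > 0
        detected_sets.append({p for p, m in zip(exp.proteins, mask) if m})

    n = len(experiments)
    counts = np.zeros((repeats, n), dtype=float)
    for r in range(repeats):
        rng = derive_rng(seed, "saturation", r)
        order = rng.permutation(n)
        seen: set[str] = set()
        for step, j in enumerate(order):
            seen |= detected_sets[int(j)]
            counts[r, step] = len(seen)

    steps = np.tile(np.arange(1, n + 1, dtype=float), repeats)
    y = counts.ravel()
    # least squares on [1, ln(step)]
    A = np.column_stack([np.ones_like(steps), np.log(steps)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return SaturationResult(counts=counts, a=float(coef[0]), b=float(coef[1]))
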