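"""Labeled training/evaluation pairs from protein-complex catalogs.

Positive examples are intra-complex pairs; negative examples are pairs of
complex-catalog proteins never found in the same complex. For non-model
species, catalogs are first projected through a one-to-one ortholog map.
Cross-validation folds are assigned at the *complex* level so that no
complex contributes pairs to more than one test fold.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterable, Optional

from ._rng import derive_rng
from .types import ComplexCatalog, LabeledPairSet, OrthologMap, Pair, make_pair

logger = logging.getLogger("cfnet.goldstandard")

__all__ = ["label_pairs", "subsample_negatives", "project_orthologs", "split_folds"]


def label_pairs(
    catalog: ComplexCatalog,
    universe: Optional[Iterable[str]] = None,
    source_tag: str = "native",
) -> LabeledPairSet:
    """Enumerate intra-complex (positive) and inter-complex (negative) pairs.

    A pair co-complexed anywhere is positive (the positive label dominates);
    negatives are pairs of catalog proteins never sharing a complex. If
    ``universe`` is given, only proteins in it participate.
    """
    if not catalog.complexes:
        raise ValueError("empty complex catalog")
    allowed = set(universe) if universe is not None else None

    positives: dict[Pair, set[str]] = {}
    for cid, members in catalog.complexes.items():
        kept = sorted(members if allowed is None else members & allowed)
        for a, b in combinations(kept, 2):
            positives.setdefault(make_pair(a, b), set()).add(cid)

    proteins = sorted(catalog.proteins if allowed is None else catalog.proteins & allowed)
    labels: dict[Pair, int] = {}
    for a, b in combinations(proteins, 2):
        pair = make_pair(a, b)
        labels[pair] = 1 if pair in positives else 0
    origin = {p: frozenset(v) for p, v in positives.items()}
    return LabeledPairSet(labels=labels, origin=origin, source_tag=source_tag)


def subsample_negatives(
    labels: LabeledPairSet, negative_ratio: float, seed: int = 0
) -> LabeledPairSet:
    """Optionally rebalance classes by keeping at most
    ``negative_ratio * n_positives`` negatives (seeded, without replacement).

    Training uses all labeled pairs by default; this is an opt-in subsampler
    for heavily imbalanced catalogs.
    """
    if negative_ratio <= 0:
        raise ValueError("negative_ratio must be > 0")
    negatives = sorted(labels.negatives)
    keep_n = int(negative_ratio * len(labels.positives))
    if keep_n >= len(negatives):
        return labels
    rng = derive_rng(seed, "negative_subsample")
    chosen = rng.choice(len(negatives), size=keep_n, replace=False)
    kept = {negatives[int(i)] for i in chosen}
    out = {p: v for p, v in labels.labels.items() if v == 1 or p in kept}
    return LabeledPairSet(labels=out, origin=dict(labels.origin), source_tag=labels.source_tag)


def project_orthologs(
    catalog: ComplexCatalog, ortholog_map: OrthologMap
) -> tuple[ComplexCatalog, dict[str, int]]:
    """Project a complex catalog into a target species via one-to-one orthologs.

    Members without a one-to-one ortholog are dropped; complexes shrinking
    below two members are dropped; complexes that become redundant after
    projection are merged into the first surviving entry. Attrition counts
    are returned alongside the projected catalog.
    """
    counts = {"members_unmapped": 0, "complexes_dropped": 0, "complexes_redundant": 0}
    projected: dict[str, frozenset[str]] = {}
    seen: dict[frozenset[str], str] = {}
    for cid in sorted(catalog.complexes):
        members = catalog.complexes[cid]
        mapped = {ortholog_map.get(m) for m in members} - {None}
        counts["members_unmapped"] += len(members) - len(mapped)
        if len(mapped) < 2:
            counts["complexes_dropped"] += 1
            continue
        key = frozenset(mapped)
        if key in seen:
            counts["complexes_redundant"] += 1
            continue
        seen[key] = cid
        projected[cid] = key
    if not projected:
        logger.warning("no complexes survived ortholog projection")
    out = ComplexCatalog(complexes=projected, source=catalog.source)
    logger.info(
        "ortholog projection: %d/%d complexes retained (%d members unmapped)",
        len(out),
        len(catalog),
        counts["members_unmapped"],
    )
    return out, counts


def split_folds(labels: LabeledPairSet, k: int, seed: int = 0) -> dict[Pair, int]:
    """Assign every labeled pair to one of ``k`` cross-validation folds.

    Complexes — not pairs — are partitioned into folds, and a positive pair
    inherits the fold of its source complex (the lexicographically smallest
    complex id if it belongs to several), preventing information leakage
    between training and test folds through shared complexes. Negatives are
    partitioned uniformly at random from the same seeded stream.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    complex_ids = sorted({cid for cids in labels.origin.values() for cid in cids})
    if k > len(complex_ids):
        raise ValueError(
            f"k={k} folds but only {len(complex_ids)} complexes contribute positives"
        )
    rng = derive_rng(seed, "fold_split")
    perm = rng.permutation(len(complex_ids))
    complex_fold = {cid: int(perm[i] % k) for i, cid in enumerate(complex_ids)}

    assignment: dict[Pair, int] = {}
    for pair in sorted(labels.positives):
        anchor = min(labels.origin[pair])
        assignment[pair] = complex_fold[anchor]
    negatives = sorted(labels.negatives)
    neg_folds = rng.integers(0, k, size=len(negatives))
    for pair, fold in zip(negatives, neg_folds):
        assignment[pair] = int(fold)
    return assignment
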