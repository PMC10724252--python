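"""Core in-memory containers shared across the cfnet pipeline.

Conventions
-----------
* A *chromatogram* is a protein's intensity vector across the fractions of a
  single CF-MS experiment. Missing values (not quantified in a fraction) are
  ``NaN`` — explicitly distinct from an intensity of 0.
* Protein pairs are always stored *alphabetized*: ``pair(a, b) == pair(b, a)``
  and ``pair[0] < pair[1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "Pair",
    "make_pair",
    "ElutionMatrix",
    "ComplexCatalog",
    "OrthologMap",
    "AnnotationSet",
    "EdgeList",
    "LabeledPairSet",
    "PhosphoSiteProfile",
    "KinaseSubstrateMap",
]

Pair = tuple[str, str]


def make_pair(a: str, b: str) -> Pair:
    """Alphabetized unordered pair. Self-pairs are rejected."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class ElutionMatrix:
    """One CF-MS experiment: a protein x fraction intensity matrix.

    Parameters
    ----------
    experiment_id : str
        Unique identifier of the experiment (replicate).
    species : str
        Species tag; used to group experiments into a study.
    proteins : list of str
        Row identifiers (protein groups or gene symbols). Unique.
    intensities : ndarray of shape (n_proteins, n_fractions)
        Non-negative intensities; ``NaN`` marks a missing (not quantified)
        value, which is distinct from 0.
    quant_type : {"intensity", "ratio"}
    """

    experiment_id: str
    species: str
    proteins: list[str]
    intensities: np.ndarray
    quant_type: str = "intensity"

    def __post_init__(self) -> None:
        self.proteins = [str(p) for p in self.proteins]
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (protein x fraction)")
        if len(self.proteins) != self.intensities.shape[0]:
            raise ValueError("protein list length does not match matrix rows")
        if self.intensities.shape[1] < 1:
            raise ValueError("at least one fraction required")
        if len(set(self.proteins)) != len(self.proteins):
            dupes = pd.Index(self.proteins)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate protein identifiers: {dupes[:5]}")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensities < 0):
                raise ValueError("negative intensity encountered")
        if self.quant_type not in ("intensity", "ratio"):
            raise ConfigError(f"unknown quant_type: {self.quant_type}")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_fractions(self) -> int:
        return int(self.intensities.shape[1])

    @property
    def fractions(self) -> np.ndarray:
        """1-based fraction indices, in file/column order."""
        return np.arange(1, self.n_fractions + 1)

    def row(self, protein: str) -> np.ndarray:
        return self.intensities[self.proteins.index(protein)]

    def detected_counts(self) -> np.ndarray:
        """Number of non-missing fractions per protein."""
        return np.sum(~np.isnan(self.intensities), axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensities,
            index=pd.Index(self.proteins, name="protein"),
            columns=[f"F{i}" for i in self.fractions],
        )


@dataclass
class ComplexCatalog:
    """A catalog of protein complexes (e.g. CORUM or EcoCyc derived).

    ``complexes`` maps complex id -> frozenset of member identifiers. Every
    complex has >= 2 members and no two complexes share an identical member
    set (redundant entries removed).
    """

    complexes: dict[str, frozenset[str]]
    source: str = "custom"

    def __post_init__(self) -> None:
        self.complexes = {str(k): frozenset(map(str, v)) for k, v in self.complexes.items()}
        for cid, members in self.complexes.items():
            if len(members) < 2:
                raise ValueError(f"complex {cid!r} has fewer than 2 members")
        seen: dict[frozenset[str], str] = {}
        for cid, members in self.complexes.items():
            if members in seen:
                raise ValueError(
                    f"redundant complexes with identical members: {seen[members]!r} and {cid!r}"
                )
            seen[members] = cid

    @property
    def proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.complexes.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.complexes)


@dataclass
class OrthologMap:
    """A one-to-one ortholog correspondence between two species.

    The mapping is injective in both directions; rows violating this are
    dropped by the reader before construction.
    """

    pairs: dict[str, str]
    policy: str = "one_to_one_only"

    def __post_init__(self) -> None:
        if self.policy != "one_to_one_only":
            raise ConfigError(f"unknown ortholog policy: {self.policy}")
        targets = list(self.pairs.values())
        if len(set(targets)) != len(targets):
            raise ValueError("ortholog map is not injective (duplicate targets)")

    def get(self, source_id: str) -> Optional[str]:
        return self.pairs.get(source_id)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AnnotationSet:
    """Term -> annotated proteins (GO terms, disease gene sets, ...)."""

    terms: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = {str(t): frozenset(map(str, v)) for t, v in self.terms.items()}
        for term, members in self.terms.items():
            if not members:
                raise ValueError(f"empty annotation term: {term!r}")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class EdgeList:
    """An undirected network as a set of alphabetized pairs, optionally scored."""

    edges: list[Pair]
    scores: Optional[dict[Pair, float]] = None

    def __post_init__(self) -> None:
        canon = []
        seen: set[Pair] = set()
        for a, b in self.edges:
            p = make_pair(str(a), str(b))
            if p not in seen:
                seen.add(p)
                canon.append(p)
        self.edges = canon
        if self.scores is not None:
            self.scores = {make_pair(*k): float(v) for k, v in self.scores.items()}

    @property
    def edge_set(self) -> frozenset[Pair]:
        return frozenset(self.edges)

    @property
    def proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return frozenset(out)

    def neighbors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {}
        for a, b in self.edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class LabeledPairSet:
    """Alphabetized pairs labeled positive (intra-complex) or negative
    (inter-complex), with per-positive provenance.

    ``labels`` maps pair -> 1 (positive) or 0 (negative). ``origin`` maps each
    positive pair to the set of complex ids that contain both members.
    """

    labels: dict[Pair, int]
    origin: dict[Pair, frozenset[str]] = field(default_factory=dict)
    source_tag: str = "native"

    def __post_init__(self) -> None:
        self.labels = {make_pair(*k): int(v) for k, v in self.labels.items()}
        for pair, lab in self.labels.items():
            if lab not in (0, 1):
                raise ValueError(f"label must be 0/1, got {lab!r} for {pair}")
        self.origin = {make_pair(*k): frozenset(v) for k, v in self.origin.items()}
        for pair in self.origin:
            if self.labels.get(pair) != 1:
                raise ValueError(f"origin recorded for non-positive pair {pair}")

    @property
    def positives(self) -> frozenset[Pair]:
        return frozenset(p for p, v in self.labels.items() if v == 1)

    @property
    def negatives(self) -> frozenset[Pair]:
        return frozenset(p for p, v in self.labels.items() if v == 0)

    def restrict(self, pairs: Iterable[Pair]) -> "LabeledPairSet":
        keep = set(pairs)
        labels = {p: v for p, v in self.labels.items() if p in keep}
        origin = {p: v for p, v in self.origin.items() if p in labels}
        return LabeledPairSet(labels=labels, origin=origin, source_tag=self.source_tag)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class PhosphoSiteProfile:
    """A phosphosite's per-fraction chromatogram within one experiment."""

    protein: str
    position: int
    residue: str
    intensities: np.ndarray
    experiment_id: str
    localization_prob: float = 1.0
    delta_score: float = float("nan")

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise ValueError(f"residue must be S/T/Y, got {self.residue!r}")
        self.position = int(self.position)
        if self.position < 1:
            raise ValueError("position is 1-based, must be >= 1")
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not (np.isnan(self.localization_prob) or 0.0 <= self.localization_prob <= 1.0):
            raise ValueError("localization probability must lie in [0, 1]")

    @property
    def site_key(self) -> tuple[str, int, str]:
        """Identity of the site across experiments."""
        return (self.protein, self.position, self.residue)

    @property
    def n_detected_fractions(self) -> int:
        return int(np.sum(~np.isnan(self.intensities)))


@dataclass
class KinaseSubstrateMap:
    """Kinase -> set of (protein, position, residue) substrate sites."""

    substrates: dict[str, frozenset[tuple[str, int, str]]]

    def __post_init__(self) -> None:
        self.substrates = {
            str(k): frozenset((str(p), int(pos), str(r)) for p, pos, r in v)
            for k, v in self.substrates.items()
        }
        for kinase, subs in self.substrates.items():
            if not subs:
                raise ValueError(f"kinase {kinase!r} has an empty substrate set")
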