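"""Synthetic CF-MS data generator with exported ground truth.

Emulates the statistical structure that co-elution network inference relies
on: members of a protein complex share a chromatographic peak within each
experiment (with per-member jitter in peak center, width and amplitude),
monomers elute independently, intensities carry multiplicative log-normal
noise, and missingness combines a detection-limit quantile (the abundance
bias of CF-MS: low-intensity values go unobserved) with random dropout.
Peak positions are redrawn per experiment; complex membership is shared
across the study.

The generator also produces annotation sets (terms = complexes plus random
terms for null testing), external labeled feature pools for augmentation and
transfer experiments, and phosphosite tables whose sites track one parent
chromatographic peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .errors import ConfigError
from .goldstandard import label_pairs
from .inference import ExternalFeaturePool
from .similarity import MeasureSpec, measure_spec, pairwise_features
from .types import AnnotationSet, ComplexCatalog, ElutionMatrix, LabeledPairSet

__all__ = [
    "SimConfig",
    "GroundTruth",
    "StudyData",
    "simulate_catalog",
    "simulate_experiment",
    "simulate_study",
    "simulate_external_pool",
    "simulate_phospho",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated CF-MS study.

    Defaults describe a small but realistic size-exclusion study: 200
    proteins, 20 complexes with geometric size tail (2-8 members), three
    replicate experiments of 50 fractions. Widths and jitter are in fraction
    units. ``detection_quantile`` is the quantile of the intensity
    distribution below which values are unobserved; ``dropout_rate`` is
    additional uniform missingness.
    """

    n_proteins: int = 200
    n_complexes: int = 20
    complex_size_min: int = 2
    complex_size_mean: float = 4.0
    complex_size_cap: int = 8
    n_experiments: int = 3
    n_fractions: int = 50
    peak_jitter_sd: float = 0.75
    peak_width_mean: float = 2.5
    peak_width_sd: float = 0.5
    amplitude_sigma: float = 0.5
    noise_sd: float = 0.3
    additive_floor: float = 0.0
    detection_quantile: float = 0.6
    dropout_rate: float = 0.1
    monomer_fraction: float = 0.5
    two_peak_fraction: float = 0.0
    n_random_terms: int = 5
    namespace: str = "P"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detection_quantile", "dropout_rate", "monomer_fraction", "two_peak_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        if self.n_fractions < 4:
            raise ConfigError("n_fractions must be >= 4 (minimum-fraction filter)")
        if self.complex_size_min < 2:
            raise ConfigError("complexes need >= 2 members")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


@dataclass
class GroundTruth:
    """What the simulator knows: the catalog, peak parameters, labels."""

    catalog: ComplexCatalog
    labels: LabeledPairSet
    # (experiment_id, protein) -> list of (center, width, amplitude) peaks
    peaks: dict[tuple[str, str], list[tuple[float, float, float]]] = field(default_factory=dict)
    two_peak_proteins: frozenset[str] = frozenset()


@dataclass
class StudyData:
    """A full simulated study: matrices plus ground truth and annotations."""

    experiments: list[ElutionMatrix]
    truth: GroundTruth
    annotations: AnnotationSet
    config: SimConfig

    @property
    def catalog(self) -> ComplexCatalog:
        return self.truth.catalog

    @property
    def labels(self) -> LabeledPairSet:
        return self.truth.labels


def simulate_catalog(config: SimConfig) -> tuple[list[str], ComplexCatalog, frozenset[str]]:
    """Protein namespace, complex membership, and the two-peak protein set.

    Proteins not assigned to a complex are monomers; at most
    ``(1 - monomer_fraction) * n_proteins`` proteins are assignable to
    complexes. Complex sizes follow ``min + (Geometric(p) - 1)`` capped at
    ``complex_size_cap`` with ``p`` set so the mean matches
    ``complex_size_mean``.
    """
    rng = derive_rng(config.seed, "catalog")
    proteins = [f"{config.namespace}{i:04d}" for i in range(config.n_proteins)]
    assignable = int(np.floor(config.n_proteins * (1.0 - config.monomer_fraction)))
    order = rng.permutation(config.n_proteins)
    pool = [proteins[int(i)] for i in order[:assignable]]

    p_geom = 1.0 / max(config.complex_size_mean - config.complex_size_min + 1.0, 1.0)
    complexes: dict[str, frozenset[str]] = {}
    cursor = 0
    for c in range(config.n_complexes):
        size = int(min(config.complex_size_min + rng.geometric(p_geom) - 1, config.complex_size_cap))
        if cursor + size > len(pool):
            break
        complexes[f"CPX{c:03d}"] = frozenset(pool[cursor : cursor + size])
        cursor += size
    catalog = ComplexCatalog(complexes=complexes, source="custom")

    n_two_peak = int(round(config.two_peak_fraction * config.n_proteins))
    two_peak = frozenset(
        proteins[int(i)] for i in rng.choice(config.n_proteins, size=n_two_peak, replace=False)
    )
    return proteins, catalog, two_peak


def _draw_member_peak(
    rng: np.random.Generator, config: SimConfig, center: float
) -> tuple[float, float, float]:
    c = center + (rng.normal(0.0, config.peak_jitter_sd) if config.peak_jitter_sd > 0 else 0.0)
    w = config.peak_width_mean + (
        rng.normal(0.0, config.peak_width_sd) if config.peak_width_sd > 0 else 0.0
    )
    w = max(w, 0.5)
    amp = float(np.exp(rng.normal(np.log(1e5), config.amplitude_sigma)))
    return (float(c), float(w), amp)


def simulate_experiment(
    config: SimConfig,
    experiment_index: int,
    proteins: Optional[list[str]] = None,
    catalog: Optional[ComplexCatalog] = None,
    two_peak: frozenset[str] = frozenset(),
) -> tuple[ElutionMatrix, dict[tuple[str, str], list[tuple[float, float, float]]]]:
    """One experiment: each complex draws a co-peak center, members get
    jittered Gaussian profiles, monomers elute independently."""
    if proteins is None or catalog is None:
        proteins, catalog, two_peak = simulate_catalog(config)
    rng = derive_rng(config.seed, "experiment", experiment_index)
    F = config.n_fractions
    exp_id = f"{config.namespace}exp{experiment_index}"
    fractions = np.arange(1, F + 1, dtype=float)

    peaks: dict[str, list[tuple[float, float, float]]] = {p: [] for p in proteins}
    for cid in sorted(catalog.complexes):
        center = rng.uniform(3.0, F - 2.0)
        for member in sorted(catalog.complexes[cid]):
            peaks[member].append(_draw_member_peak(rng, config, center))
    in_complex = catalog.proteins
    for protein in proteins:
        if protein not in in_complex:
            center = rng.uniform(3.0, F - 2.0)
            peaks[protein].append(_draw_member_peak(rng, config, center))
    for protein in sorted(two_peak):
        center = rng.uniform(3.0, F - 2.0)
        c, w, amp = _draw_member_peak(rng, config, center)
        primary_amp = peaks[protein][0][2]
        peaks[protein].append((c, w, primary_amp * rng.uniform(0.3, 0.7)))

    values = np.zeros((len(proteins), F))
    for i, protein in enumerate(proteins):
        for c, w, amp in peaks[protein]:
            values[i] += amp * np.exp(-0.5 * ((fractions - c) / w) ** 2)
    if config.noise_sd > 0:
        values *= np.exp(rng.normal(0.0, config.noise_sd, size=values.shape))
    if config.additive_floor > 0:
        values += np.abs(rng.normal(0.0, config.additive_floor, size=values.shape))

    missing = np.zeros(values.shape, dtype=bool)
    if config.detection_quantile > 0:
        limit = np.quantile(values, config.detection_quantile)
        missing |= values < limit
    if config.dropout_rate > 0:
        missing |= rng.random(values.shape) < config.dropout_rate
    values = values.copy()
    values[missing] = np.nan

    matrix = ElutionMatrix(
        experiment_id=exp_id,
        species=f"sim_{config.namespace}",
        proteins=list(proteins),
        intensities=values,
    )
    truth_slice = {(exp_id, p): peaks[p] for p in proteins}
    return matrix, truth_slice


def simulate_study(config: SimConfig) -> StudyData:
    """A multi-replicate study sharing complex membership across experiments.

    Annotation terms are generated from the true complexes (one term per
    complex) plus ``n_random_terms`` random protein sets for null testing.
    """
    proteins, catalog, two_peak = simulate_catalog(config)
    experiments = []
    peaks: dict[tuple[str, str], list[tuple[float, float, float]]] = {}
    for e in range(config.n_experiments):
        matrix, truth_slice = simulate_experiment(
            config, e, proteins=proteins, catalog=catalog, two_peak=two_peak
        )
        experiments.append(matrix)
        peaks.update(truth_slice)
    labels = label_pairs(catalog)

    terms = {f"T_{cid}": members for cid, members in catalog.complexes.items()}
    rng = derive_rng(config.seed, "annotations")
    for t in range(config.n_random_terms):
        size = int(rng.integers(5, 16))
        members = rng.choice(config.n_proteins, size=min(size, config.n_proteins), replace=False)
        terms[f"RND{t:03d}"] = frozenset(proteins[int(i)] for i in members)
    annotations = AnnotationSet(terms=terms)

    truth = GroundTruth(catalog=catalog, labels=labels, peaks=peaks, two_peak_proteins=two_peak)
    return StudyData(experiments=experiments, truth=truth, annotations=annotations, config=config)


def simulate_external_pool(
    config: SimConfig,
    n_external_experiments: int,
    measures: Sequence[str] = ("dcor",),
    namespace: str = "X",
) -> tuple[ExternalFeaturePool, StudyData]:
    """An independent external study in a disjoint protein namespace, with
    per-experiment feature rows for its labeled pairs.

    Mirrors the role of large external CF-MS corpora: features (distance
    correlation by default) computed for all labeled pairs of the external
    species, to be injected into a target species' training data or used to
    train a transfer classifier.
    """
    ext_config = replace(
        config,
        n_experiments=n_external_experiments,
        namespace=namespace,
        seed=int(derive_rng(config.seed, "external_pool").integers(0, 2**31 - 1)),
    )
    study = simulate_study(ext_config)
    specs: list[MeasureSpec] = [measure_spec(m) for m in measures]
    catalog_proteins = sorted(study.catalog.proteins)
    labeled = set(study.labels.labels)

    experiments: dict[str, pd.DataFrame] = {}
    for matrix in study.experiments:
        keep = [i for i, p in enumerate(matrix.proteins) if p in study.catalog.proteins]
        sub = ElutionMatrix(
            experiment_id=matrix.experiment_id,
            species=matrix.species,
            proteins=[matrix.proteins[i] for i in keep],
            intensities=matrix.intensities[keep],
        )
        feats = pairwise_features(sub, specs, seed=ext_config.seed)
        feats = feats.loc[[p for p in feats.index if p in labeled]]
        experiments[matrix.experiment_id] = feats
    pool = ExternalFeaturePool(experiments=experiments, labels=dict(study.labels.labels))
    return pool, study


def simulate_phospho(
    study: StudyData,
    sites_per_protein_rate: float = 0.3,
    residue_probs: tuple[float, float, float] = (0.65, 0.20, 0.15),
    experiment_index: int = 0,
    site_dropout: float = 0.3,
    max_position: int = 4000,
) -> tuple[pd.DataFrame, dict[tuple[str, int, str], dict]]:
    """Phosphosite table for one experiment of a simulated study.

    Each protein receives ``Poisson(rate)`` sites. A site's intensity follows
    the parent profile restricted to *one* parent chromatographic peak
    (enabling peak-specificity analyses), scaled by a per-site stoichiometry,
    with heavier missingness than the parent. ``residue_probs`` is the
    (pS, pT, pY) simplex. Returns the typed site table (the schema of
    :func:`cfnet.io_formats.read_phospho_sites`) and per-site ground truth
    including the assigned parent peak (1-based).
    """
    if abs(sum(residue_probs) - 1.0) > 1e-9:
        raise ConfigError("residue_probs must sum to 1")
    config = study.config
    matrix = study.experiments[experiment_index]
    rng = derive_rng(config.seed, "phospho", experiment_index)
    fractions = np.arange(1, config.n_fractions + 1, dtype=float)
    residues = np.array(["S", "T", "Y"])

    rows = []
    truth: dict[tuple[str, int, str], dict] = {}
    for protein in matrix.proteins:
        n_sites = int(rng.poisson(sites_per_protein_rate))
        if n_sites == 0:
            continue
        peaks = study.truth.peaks[(matrix.experiment_id, protein)]
        positions = rng.choice(max_position, size=min(n_sites, max_position), replace=False) + 1
        parent_row = matrix.row(protein)
        for pos in positions:
            residue = str(rng.choice(residues, p=list(residue_probs)))
            peak_idx = int(rng.integers(0, len(peaks)))
            c, w, amp = peaks[peak_idx]
            stoich = rng.uniform(0.05, 0.5)
            profile = stoich * amp * np.exp(-0.5 * ((fractions - c) / w) ** 2)
            if config.noise_sd > 0:
                profile = profile * np.exp(rng.normal(0.0, config.noise_sd, size=profile.shape))
            missing = np.isnan(parent_row)  # site undetectable where parent is
            if config.detection_quantile > 0:
                observed = profile[~missing]
                if observed.size:
                    missing |= profile < np.quantile(observed, config.detection_quantile)
            missing |= rng.random(profile.shape) < site_dropout
            intensities = profile.copy()
            intensities[missing] = np.nan
            key = (protein, int(pos), residue)
            truth[key] = {"peak": peak_idx + 1, "stoichiometry": float(stoich)}
            row = {
                "protein": protein,
                "position": int(pos),
                "residue": residue,
                "localization_prob": float(rng.uniform(0.7, 1.0)),
                "delta_score": float(rng.uniform(6.0, 120.0)),
                "reverse": False,
                "contaminant": False,
            }
            for j, v in enumerate(intensities, start=1):
                row[f"intensity_{j}"] = v
            rows.append(row)
    columns = [
        "protein",
        "position",
        "residue",
        "localization_prob",
        "delta_score",
        "reverse",
        "contaminant",
    ] + [f"intensity_{j}" for j in range(1, config.n_fractions + 1)]
    table = pd.DataFrame.from_records(rows, columns=columns)
    return table, truth
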