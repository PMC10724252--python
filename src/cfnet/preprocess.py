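"""Chromatogram quality control and gene-level collapsing.

The fixed pipeline order is: flag filtering -> zero-to-missing conversion
(MaxQuant dialect) -> gene collapsing -> minimum-fraction filter. A provenance
log records how many rows each rule removed, so that
``rows_in - rows_out == sum(removals)`` always holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .types import ElutionMatrix

logger = logging.getLogger("cfnet.preprocess")

__all__ = [
    "CleanExperiment",
    "filter_flagged",
    "zeros_to_missing",
    "collapse_to_genes",
    "filter_min_fractions",
    "preprocess_experiment",
]


@dataclass
class CleanExperiment:
    """A quality-controlled experiment plus its provenance log."""

    matrix: ElutionMatrix
    provenance: dict[str, int] = field(default_factory=dict)
    gene_map: dict[str, str] = field(default_factory=dict)


def _subset(matrix: ElutionMatrix, keep: np.ndarray) -> ElutionMatrix:
    keep = np.asarray(keep, dtype=bool)
    return ElutionMatrix(
        experiment_id=matrix.experiment_id,
        species=matrix.species,
        proteins=[p for p, k in zip(matrix.proteins, keep) if k],
        intensities=matrix.intensities[keep],
        quant_type=matrix.quant_type,
    )


def filter_flagged(
    matrix: ElutionMatrix, flags: Optional[pd.DataFrame]
) -> tuple[ElutionMatrix, dict[str, int]]:
    """Remove contaminants, reverse hits and only-identified-by-site rows.

    ``flags`` is the boolean frame attached by the reader (columns
    ``reverse``, ``contaminant``, ``only_by_site``), indexed by protein.
    Absent flags remove nothing (a warning is logged by the reader). An
    all-flagged input yields an empty matrix, not an error.
    """
    counts = {"reverse": 0, "contaminant": 0, "only_by_site": 0}
    if flags is None:
        logger.warning("%s: no flag columns; nothing removed", matrix.experiment_id)
        return matrix, counts
    flags = flags.reindex(pd.Index(matrix.proteins), fill_value=False)
    removed = np.zeros(matrix.n_proteins, dtype=bool)
    # Attribute each removed row to the first rule that flags it, so counts sum.
    for rule in ("reverse", "contaminant", "only_by_site"):
        if rule not in flags.columns:
            continue
        hit = flags[rule].to_numpy(dtype=bool) & ~removed
        counts[rule] = int(hit.sum())
        removed |= hit
    if removed.all() and matrix.n_proteins:
        logger.warning("%s: every row was flagged; matrix is empty", matrix.experiment_id)
    return _subset(matrix, ~removed), counts


def zeros_to_missing(matrix: ElutionMatrix) -> ElutionMatrix:
    """Convert exact zeros to missing values.

    MaxQuant writes 0 for "not quantified", whereas the simulator and the
    generic TSV dialect distinguish missing from zero; this conversion is on
    by default for the proteinGroups dialect.
    """
    values = matrix.intensities.copy()
    values[values == 0.0] = np.nan
    return ElutionMatrix(
        experiment_id=matrix.experiment_id,
        species=matrix.species,
        proteins=list(matrix.proteins),
        intensities=values,
        quant_type=matrix.quant_type,
    )


def collapse_to_genes(
    matrix: ElutionMatrix, gene_map: dict[str, str]
) -> tuple[ElutionMatrix, dict[str, int], dict[str, str]]:
    """Map protein groups to gene symbols; one chromatogram per gene.

    Among rows mapping to the same gene the row with the fewest missing
    fractions is kept; ties are broken by larger summed intensity, then by
    lexicographic group id (deterministic regardless of input row order).
    Rows without a gene mapping are dropped with a count.
    """
    n_missing = np.sum(np.isnan(matrix.intensities), axis=1)
    with np.errstate(invalid="ignore"):
        totals = np.nansum(matrix.intensities, axis=1)

    best: dict[str, tuple[float, float, str, int]] = {}
    unmapped = 0
    for i, group in enumerate(matrix.proteins):
        gene = gene_map.get(group)
        if gene is None:
            unmapped += 1
            continue
        # Sort key: fewest missing, then largest total, then smallest group id.
        key = (float(n_missing[i]), -float(totals[i]), group)
        if gene not in best or key < best[gene][:3]:
            best[gene] = (*key, i)

    order = sorted(best.items(), key=lambda kv: kv[1][3])
    keep_idx = [i for _, (_, _, _, i) in order]
    genes = [g for g, _ in order]
    chosen_groups = {genes[k]: matrix.proteins[i] for k, i in enumerate(keep_idx)}
    collapsed = ElutionMatrix(
        experiment_id=matrix.experiment_id,
        species=matrix.species,
        proteins=genes,
        intensities=matrix.intensities[keep_idx] if keep_idx else
        np.empty((0, matrix.n_fractions)),
        quant_type=matrix.quant_type,
    )
    counts = {
        "unmapped": unmapped,
        "collapsed_duplicates": matrix.n_proteins - unmapped - collapsed.n_proteins,
    }
    used_map = {group: gene for gene, group in chosen_groups.items()}
    return collapsed, counts, used_map


def filter_min_fractions(
    matrix: ElutionMatrix, min_fractions: int = 4
) -> tuple[ElutionMatrix, dict[str, int]]:
    """Drop proteins quantified in fewer than ``min_fractions`` fractions.

    The boundary is inclusive: a protein detected in exactly ``min_fractions``
    fractions is retained. Default 4.
    """
    if min_fractions < 1:
        raise ValueError("min_fractions must be >= 1")
    detected = matrix.detected_counts()
    keep = detected >= min_fractions
    return _subset(matrix, keep), {"below_min_fractions": int((~keep).sum())}


def preprocess_experiment(
    matrix: ElutionMatrix,
    flags: Optional[pd.DataFrame] = None,
    gene_map: Optional[dict[str, str]] = None,
    min_fractions: int = 4,
    zeros_are_missing: bool = True,
) -> CleanExperiment:
    """Full QC pipeline: flags -> zeros-to-missing -> gene collapse -> min-fraction filter."""
    rows_in = matrix.n_proteins
    provenance: dict[str, int] = {"rows_in": rows_in}
    matrix, flag_counts = filter_flagged(matrix, flags)
    provenance.update(flag_counts)
    if zeros_are_missing:
        matrix = zeros_to_missing(matrix)
    used_map: dict[str, str] = {}
    if gene_map is not None:
        matrix, collapse_counts, used_map = collapse_to_genes(matrix, gene_map)
        provenance.update(collapse_counts)
    matrix, frac_counts = filter_min_fractions(matrix, min_fractions=min_fractions)
    provenance.update(frac_counts)
    provenance["rows_out"] = matrix.n_proteins
    return CleanExperiment(matrix=matrix, provenance=provenance, gene_map=used_map)
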