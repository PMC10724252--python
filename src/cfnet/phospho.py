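"""Phosphosite-level meta-analysis of CF-MS data.

Sites from MaxQuant ``Phospho (STY)Sites.txt``-dialect tables are filtered
(reverse hits, contaminants), tracked across fractions and experiments, and
prioritized by a detection heuristic: a phosphosite quantified in at least
five CF-MS fractions is a candidate regulatory site. Kinase-substrate
enrichment among prioritized sites uses the upper-tail hypergeometric test
against the background of all sites ever detected, with Benjamini-Hochberg
correction. Stoichiometry chromatograms (modified/unmodified intensity
ratios) and a parent-peak assignment flag support peak-specificity analyses.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import ElutionMatrix, KinaseSubstrateMap, PhosphoSiteProfile

logger = logging.getLogger("cfnet.phospho")

SiteKey = tuple[str, int, str]

__all__ = [
    "filter_sites",
    "detection_counts",
    "prioritize",
    "residue_proportions",
    "ksea_hypergeometric",
    "stoichiometry_profile",
]


def filter_sites(raw: pd.DataFrame, experiment_id: str = "") -> list[PhosphoSiteProfile]:
    """Convert a raw phosphosite table into profiles, dropping flagged rows.

    ``raw`` is the typed frame from :func:`cfnet.io_formats.read_phospho_sites`.
    Rows flagged reverse or contaminant are removed with counts logged; an
    all-flagged table yields an empty list with a warning, not an error.
    """
    intensity_cols = [c for c in raw.columns if c.startswith("intensity_")]
    n_rev = int(raw["reverse"].sum()) if "reverse" in raw.columns else 0
    n_con = 0
    profiles: list[PhosphoSiteProfile] = []
    for _, row in raw.iterrows():
        if row.get("reverse", False):
            continue
        if row.get("contaminant", False):
            n_con += 1
            continue
        intensities = np.array([row[c] for c in intensity_cols], dtype=float)
        profiles.append(
            PhosphoSiteProfile(
                protein=row["protein"],
                position=int(row["position"]),
                residue=row["residue"],
                intensities=intensities,
                experiment_id=experiment_id,
                localization_prob=float(row.get("localization_prob", np.nan)),
                delta_score=float(row.get("delta_score", np.nan)),
            )
        )
    if n_rev or n_con:
        logger.info("filtered %d reverse and %d contaminant phosphosite rows", n_rev, n_con)
    if not profiles and len(raw):
        logger.warning("every phosphosite row was flagged; returning an empty site list")
    return profiles


def detection_counts(sites: Iterable[PhosphoSiteProfile]) -> pd.DataFrame:
    """Per-site detection counts across fractions and experiments.

    Sites are identified by (protein, position, residue). ``n_fractions`` is
    the total number of non-missing intensity cells across all experiments;
    ``n_experiments`` counts experiments with at least one detected fraction.
    An aggregate-only quantification (no per-fraction values) counts as one
    experiment and zero fractions.
    """
    frac: dict[SiteKey, int] = {}
    exps: dict[SiteKey, set[str]] = {}
    for site in sites:
        key = site.site_key
        n = site.n_detected_fractions
        frac[key] = frac.get(key, 0) + n
        exps.setdefault(key, set()).add(site.experiment_id)
    records = [
        {
            "protein": k[0],
            "position": k[1],
            "residue": k[2],
            "n_fractions": frac[k],
            "n_experiments": len(exps[k]),
        }
        for k in sorted(frac)
    ]
    return pd.DataFrame.from_records(
        records, columns=["protein", "position", "residue", "n_fractions", "n_experiments"]
    )


def prioritize(counts: pd.DataFrame, min_fractions: int = 5) -> pd.DataFrame:
    """Sites detected in at least ``min_fractions`` fractions (inclusive)."""
    return counts[counts["n_fractions"] >= min_fractions].reset_index(drop=True)


def residue_proportions(sites: pd.DataFrame | Iterable[PhosphoSiteProfile]) -> dict[str, float]:
    """Proportions of pS/pT/pY among unique sites (each counted once)."""
    if isinstance(sites, pd.DataFrame):
        keys = {
            (r.protein, r.position, r.residue) for r in sites.itertuples(index=False)
        }
    else:
        keys = {s.site_key for s in sites}
    if not keys:
        raise ValueError("no phosphosites to summarize")
    total = len(keys)
    return {
        res: sum(1 for k in keys if k[2] == res) / total for res in ("S", "T", "Y")
    }


def ksea_hypergeometric(
    foreground: Iterable[SiteKey],
    background: Iterable[SiteKey],
    kinase_map: KinaseSubstrateMap,
) -> pd.DataFrame:
    """Kinase-substrate enrichment among prioritized sites.

    For each kinase, the upper-tail hypergeometric probability
    ``P(X >= k)`` of drawing ``k`` of the kinase's substrate sites in
    ``|foreground|`` draws from the ``|background|`` population (successes =
    substrates present in the background). Kinases without background
    substrates are skipped. Benjamini-Hochberg q-values are reported across
    the tested kinases alongside the raw p-values.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground sites must be a subset of the background")
    M = len(bg)
    n_draw = len(fg)
    rows = []
    for kinase in sorted(kinase_map.substrates):
        subs_bg = kinase_map.substrates[kinase] & bg
        K = len(subs_bg)
        if K == 0:
            logger.info("kinase %r has no background substrates; skipped", kinase)
            continue
        k_obs = len(subs_bg & fg)
        p = float(hypergeom.sf(k_obs - 1, M, K, n_draw))
        rows.append(
            {
                "kinase": kinase,
                "overlap": k_obs,
                "n_substrates_background": K,
                "expected": K * n_draw / M,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame.from_records(
        rows,
        columns=["kinase", "overlap", "n_substrates_background", "expected", "p_value"],
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df


def _parent_peaks(parent: np.ndarray, smooth_window: int, min_prominence_frac: float) -> list[int]:
    """Local maxima of a parent chromatogram (0-based fraction indices).

    Missing values are treated as zero intensity, the trace smoothed with a
    centered moving average, and peaks below a prominence floor (fraction of
    the smoothed maximum) discarded. If no interior peak survives, the global
    maximum is the single peak.
    """
    trace = np.nan_to_num(parent, nan=0.0)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        trace = np.convolve(trace, kernel, mode="same")
    if trace.max() <= 0:
        return []
    peaks, _ = find_peaks(trace, prominence=min_prominence_frac * trace.max())
    if peaks.size == 0:
        return [int(np.argmax(trace))]
    return [int(p) for p in peaks]


def stoichiometry_profile(
    site: PhosphoSiteProfile,
    parent: np.ndarray | ElutionMatrix,
    smooth_window: int = 3,
    min_prominence_frac: float = 0.1,
) -> tuple[np.ndarray, Optional[int]]:
    """Modified/unmodified intensity-ratio chromatogram plus peak assignment.

    Returns the per-fraction stoichiometry (site intensity divided by the
    parent-protein intensity, where both are defined) and a 1-based flag
    identifying which parent chromatographic peak the site's intensity
    maximum co-locates with (nearest fraction). The flag is ``None`` when the
    site and parent share no quantified fraction.
    """
    if isinstance(parent, ElutionMatrix):
        parent = parent.row(site.protein)
    parent = np.asarray(parent, dtype=float)
    if parent.shape != site.intensities.shape:
        raise ValueError("site and parent chromatograms differ in length")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(
            ~np.isnan(site.intensities) & ~np.isnan(parent) & (parent > 0),
            site.intensities / parent,
            np.nan,
        )
    both = ~np.isnan(site.intensities) & ~np.isnan(parent)
    if not both.any():
        logger.info(
            "site %s has no fraction overlapping its parent; peak flag undefined",
            site.site_key,
        )
        return ratios, None
    peaks = _parent_peaks(parent, smooth_window, min_prominence_frac)
    if not peaks:
        return ratios, None
    site_max = int(np.nanargmax(site.intensities))
    nearest = int(np.argmin([abs(site_max - p) for p in peaks]))
    return ratios, nearest + 1
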