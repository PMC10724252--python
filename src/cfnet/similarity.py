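"""Chromatogram-similarity measures with their missing-value strategies.

Four measures, in descending order of how well they separate intra- from
inter-complex pairs in large-scale CF-MS benchmarks, each bound to a specific
missing-value strategy:

===================================  =========================
measure                              missing-value strategy
===================================  =========================
distance correlation (``dcor``)      impute as zeros
weighted cross-correlation (``wcc``) impute as zeros
cosine similarity (``cosine``)       impute as near-zero noise
mutual information (``mi``)          pairwise-complete (NAs)
===================================  =========================

Pearson correlation (pairwise-complete) is additionally provided for
evaluation uses. Scalar functions operate on two 1-D chromatograms; the
vectorized ``pairwise_features`` computes all protein pairs of an experiment
at once and is numerically identical to the scalar path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .errors import ConfigError
from .types import ElutionMatrix

logger = logging.getLogger("cfnet.similarity")

__all__ = [
    "MeasureSpec",
    "OPTIMAL_MEASURE_ORDER",
    "measure_spec",
    "impute",
    "distance_correlation",
    "weighted_cross_correlation",
    "cosine",
    "mutual_information",
    "pearson",
    "pairwise_features",
]

#: The optimal measures in descending order of benchmark performance.
OPTIMAL_MEASURE_ORDER: tuple[str, ...] = ("dcor", "wcc", "cosine", "mi")

_MV_BINDING = {
    "dcor": "zeros",
    "wcc": "zeros",
    "cosine": "near_zero_noise",
    "mi": "na_pairwise",
    "pearson": "na_pairwise",
}

_DEFAULT_PARAMS = {
    "dcor": {},
    "wcc": {"L": 1},
    "cosine": {"sigma": 1e-4},
    "mi": {"B": 10},
    "pearson": {},
}


@dataclass(frozen=True)
class MeasureSpec:
    """A similarity measure bound to its missing-value strategy and parameters."""

    measure: str
    mv_strategy: str
    params: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.measure not in _MV_BINDING:
            raise ConfigError(f"unknown measure: {self.measure!r}")
        if self.mv_strategy != _MV_BINDING[self.measure]:
            raise ConfigError(
                f"measure {self.measure!r} requires mv_strategy "
                f"{_MV_BINDING[self.measure]!r}, got {self.mv_strategy!r}"
            )
        for key, value in self.params:
            if value <= 0:
                raise ConfigError(f"parameter {key}={value} must be positive")

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(self.params)


def measure_spec(measure: str, **params: float) -> MeasureSpec:
    """Build the canonical :class:`MeasureSpec` for a measure name."""
    merged = {**_DEFAULT_PARAMS.get(measure, {}), **params}
    return MeasureSpec(
        measure=measure,
        mv_strategy=_MV_BINDING.get(measure, ""),
        params=tuple(sorted(merged.items())),
    )


# ---------------------------------------------------------------------------
# Missing-value handling
# ---------------------------------------------------------------------------


def impute(
    x: Sequence[float],
    strategy: str,
    sigma: float = 1e-4,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Apply a missing-value strategy to a single chromatogram.

    ``zeros``
        missing -> 0.
    ``near_zero_noise``
        missing -> i.i.d. half-normal draws scaled to ``sigma * max_observed``
        from a seeded stream (deterministic for a fixed seed).
    ``na_pairwise``
        identity; downstream measures use pairwise-complete positions.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("chromatogram must have length >= 1")
    missing = np.isnan(x)
    if strategy == "na_pairwise" or not missing.any():
        return x.copy()
    if strategy == "zeros":
        out = x.copy()
        out[missing] = 0.0
        return out
    if strategy == "near_zero_noise":
        if missing.all():
            raise ValueError("near_zero_noise imputation needs >=1 observed value")
        scale = sigma * np.nanmax(x)
        if rng is None:
            rng = derive_rng(seed, "near_zero_noise")
        out = x.copy()
        out[missing] = np.abs(rng.normal(0.0, scale, size=int(missing.sum())))
        return out
    raise ConfigError(f"unknown missing-value strategy: {strategy!r}")


# ---------------------------------------------------------------------------
# Scalar measures
# ---------------------------------------------------------------------------


def _dcenter(d: np.ndarray) -> np.ndarray:
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Szekely distance correlation in [0, 1]; missing values imputed as zeros.

    Computed from doubly-centered pairwise-distance matrices. Returns 0 if
    either distance variance vanishes (constant chromatogram).
    """
    x = impute(x, "zeros")
    y = impute(y, "zeros")
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need n >= 2")
    a = _dcenter(np.abs(x[:, None] - x[None, :]))
    b = _dcenter(np.abs(y[:, None] - y[None, :]))
    dvar_x = (a * a).mean()
    dvar_y = (b * b).mean()
    if dvar_x <= 0.0 or dvar_y <= 0.0:
        return 0.0
    dcov2 = (a * b).mean()
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


def weighted_cross_correlation(x: Sequence[float], y: Sequence[float], L: int = 1) -> float:
    """Weighted cross-correlation over lags -L..L with triangular weights.

    WCC = sum_k w_k c_k(x,y) / sqrt(sum_k w_k c_k(x,x) * sum_k w_k c_k(y,y)),
    where ``c_k`` is the raw cross-covariance of the mean-centered,
    zero-imputed chromatograms at lag ``k`` and ``w_k = 1 - |k|/(L+1)``.
    Reduces to the Pearson correlation of the centered vectors at ``L = 0``.
    A vanishing denominator yields 0 with a warning.
    """
    x = impute(x, "zeros")
    y = impute(y, "zeros")
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if not n > L >= 0:
        raise ValueError(f"need n > L >= 0 (n={n}, L={L})")
    xc = x - x.mean()
    yc = y - y.mean()

    def c(u: np.ndarray, v: np.ndarray, k: int) -> float:
        # raw cross-covariance at lag k: sum_t u[t] v[t+k]
        if k >= 0:
            return float(u[: n - k] @ v[k:])
        return float(u[-k:] @ v[: n + k])

    num = sxx = syy = 0.0
    for k in range(-L, L + 1):
        w = 1.0 - abs(k) / (L + 1.0)
        num += w * c(xc, yc, k)
        sxx += w * c(xc, xc, k)
        syy += w * c(yc, yc, k)
    den = sxx * syy
    if den <= 0.0:
        logger.warning("WCC denominator vanished; returning 0")
        return 0.0
    return float(num / math.sqrt(den))


def cosine(x: Sequence[float], y: Sequence[float]) -> float:
    """Cosine similarity of two imputed chromatograms.

    Inputs must already be free of missing values (apply near-zero-noise
    imputation first); a zero-norm vector is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("cosine requires imputed (complete) chromatograms")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("zero-norm chromatogram")
    return float(x @ y / (nx * ny))


def _bin_indices(v: np.ndarray, B: int) -> np.ndarray:
    """Equal-width bin index in 0..B-1 over the observed range of ``v``."""
    lo = v.min()
    hi = v.max()
    if hi == lo:
        return np.zeros(v.size, dtype=np.intp)
    idx = np.floor((v - lo) / (hi - lo) * B).astype(np.intp)
    return np.minimum(idx, B - 1)


def mutual_information(x: Sequence[float], y: Sequence[float], B: int = 10) -> float:
    """Plug-in mutual information (nats) over a BxB equal-width histogram.

    Missing values are handled pairwise-complete; fewer than ``B`` complete
    positions yields NaN (the missing-feature marker).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    ok = ~(np.isnan(x) | np.isnan(y))
    if int(ok.sum()) < B:
        return float("nan")
    xv = x[ok]
    yv = y[ok]
    bx = _bin_indices(xv, B)
    by = _bin_indices(yv, B)
    joint = np.bincount(bx * B + by, minlength=B * B).astype(float).reshape(B, B)
    n = xv.size
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(px, py)
    return float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation over pairwise-complete positions (NaN if < 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    ok = ~(np.isnan(x) | np.isnan(y))
    if int(ok.sum()) < 3:
        return float("nan")
    xv = x[ok] - x[ok].mean()
    yv = y[ok] - y[ok].mean()
    den = np.sqrt((xv @ xv) * (yv @ yv))
    if den == 0.0:
        return float("nan")
    return float(xv @ yv / den)


# ---------------------------------------------------------------------------
# Vectorized all-pairs computation
# ---------------------------------------------------------------------------


def _impute_matrix(matrix: ElutionMatrix, strategy: str, sigma: float, seed: int) -> np.ndarray:
    """Row-wise imputation; the noise stream is keyed by (seed, experiment,
    protein) so the cosine feature is deterministic end-to-end."""
    out = matrix.intensities.copy()
    if strategy == "zeros":
        out[np.isnan(out)] = 0.0
        return out
    if strategy == "near_zero_noise":
        for i, protein in enumerate(matrix.proteins):
            row = out[i]
            if np.isnan(row).any():
                rng = derive_rng(seed, "near_zero_noise", matrix.experiment_id, protein)
                out[i] = impute(row, "near_zero_noise", sigma=sigma, rng=rng)
        return out
    if strategy == "na_pairwise":
        return out
    raise ConfigError(f"unknown missing-value strategy: {strategy!r}")


def _pairwise_dcor(X: np.ndarray) -> np.ndarray:
    p, n = X.shape
    flat = np.empty((p, n * n))
    for i in range(p):
        flat[i] = _dcenter(np.abs(X[i][:, None] - X[i][None, :])).ravel()
    gram = (flat @ flat.T) / (n * n)  # dCov^2 between all rows
    dvar = np.diag(gram).copy()
    ok = dvar > 0
    denom = np.sqrt(np.outer(dvar, dvar))
    with np.errstate(invalid="ignore", divide="ignore"):
        dcor = np.sqrt(np.maximum(gram, 0.0) / denom)
    dcor[~ok, :] = 0.0
    dcor[:, ~ok] = 0.0
    return dcor


def _pairwise_wcc(X: np.ndarray, L: int) -> np.ndarray:
    n = X.shape[1]
    if not n > L >= 0:
        raise ValueError(f"need n > L >= 0 (n={n}, L={L})")
    Xc = X - X.mean(axis=1, keepdims=True)
    S = Xc @ Xc.T  # lag 0, weight 1
    for k in range(1, L + 1):
        w = 1.0 - k / (L + 1.0)
        Ck = Xc[:, : n - k] @ Xc[:, k:].T
        S += w * (Ck + Ck.T)
    d = np.diag(S).copy()
    ok = d > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = S / np.sqrt(np.outer(d, d))
    out[~ok, :] = 0.0
    out[:, ~ok] = 0.0
    return out


def _pairwise_cosine(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    ok = norms > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (X @ X.T) / np.outer(norms, norms)
    out[~ok, :] = np.nan
    out[:, ~ok] = np.nan
    return out


def pairwise_features(
    experiment: ElutionMatrix,
    specs: Sequence[MeasureSpec],
    seed: int = 0,
) -> pd.DataFrame:
    """Compute every measure for every protein pair of one experiment.

    Returns a DataFrame indexed by alphabetized pair tuples with one column
    per measure. NaN is the missing-feature marker (e.g. mutual information
    with insufficient pairwise-complete overlap).
    """
    proteins = sorted(experiment.proteins)
    idx = {p: experiment.proteins.index(p) for p in proteins}
    pairs = list(combinations(proteins, 2))
    out = pd.DataFrame(index=pd.Index(pairs, tupleize_cols=False), dtype=float)

    for spec in specs:
        params = spec.param_dict
        if spec.measure == "dcor":
            X = _impute_matrix(experiment, "zeros", 0.0, seed)
            M = _pairwise_dcor(X)
        elif spec.measure == "wcc":
            X = _impute_matrix(experiment, "zeros", 0.0, seed)
            M = _pairwise_wcc(X, L=int(params.get("L", 1)))
        elif spec.measure == "cosine":
            X = _impute_matrix(
                experiment, "near_zero_noise", float(params.get("sigma", 1e-4)), seed
            )
            M = _pairwise_cosine(X)
        elif spec.measure in ("mi", "pearson"):
            X = experiment.intensities
            p = len(experiment.proteins)
            M = np.full((p, p), np.nan)
            func = (
                (lambda a, b: mutual_information(a, b, B=int(params.get("B", 10))))
                if spec.measure == "mi"
                else pearson
            )
            for i in range(p):
                for j in range(i + 1, p):
                    M[i, j] = M[j, i] = func(X[i], X[j])
        else:  # pragma: no cover - guarded by MeasureSpec
            raise ConfigError(f"unknown measure: {spec.measure!r}")
        out[spec.measure] = [M[idx[a], idx[b]] for a, b in pairs]
    return out
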