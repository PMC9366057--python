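"""Group-wise Pearson correlation matrices and a permutation equality test.

The contrast of interest is whether the two diagnostic groups share one
correlation structure over the 13 scales.  The global test permutes group
labels over the pooled rows and compares the Frobenius norm of the
off-diagonal correlation difference against its permutation null, with the
add-one convention p = (1 + #{perm >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

__all__ = [
    "CorrelationComparison",
    "pearson_matrix",
    "correlation_difference",
    "permutation_equality_test",
]


@dataclass(frozen=True)
class CorrelationComparison:
    """Paired correlation matrices, their difference and the permutation test."""

    corr_a: np.ndarray
    corr_b: np.ndarray
    difference: np.ndarray
    statistic: float
    p_value: float
    n_perm: int
    statistic_name: str = "frobenius"


def _to_matrix(data) -> np.ndarray:
    x = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) \
        else np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be two-dimensional")
    return x


def _fast_corr(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", xc, xc))
    xc = xc / norms
    c = xc.T @ xc
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def pearson_matrix(data, columns=None) -> np.ndarray:
    """Pearson correlation matrix (symmetric, unit diagonal)."""
    x = _to_matrix(data)
    if x.shape[0] < 3:
        raise InsufficientDataError("need n >= 3 rows")
    sds = x.std(axis=0)
    if np.any(sds == 0):
        names = (list(data.columns) if isinstance(data, pd.DataFrame)
                 else columns or list(range(x.shape[1])))
        bad = [str(names[i]) for i in np.flatnonzero(sds == 0)]
        raise InsufficientDataError(f"zero-variance column(s): {bad}")
    return _fast_corr(x)


def correlation_difference(corr_a: np.ndarray, corr_b: np.ndarray) -> np.ndarray:
    """Elementwise ``corr_a - corr_b`` (antisymmetric under argument swap)."""
    a = np.asarray(corr_a, dtype=float)
    b = np.asarray(corr_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("conformable square matrices required")
    return a - b


def _statistic(diff: np.ndarray, name: str) -> float:
    off = diff.copy()
    np.fill_diagonal(off, 0.0)
    if name == "frobenius":
        return float(np.linalg.norm(off, "fro"))
    if name == "max-abs":
        return float(np.max(np.abs(off)))
    raise ValueError(f"unknown statistic {name!r}")


def permutation_equality_test(group_a, group_b, n_perm: int = 10000,
                              seed: int = 0,
                              statistic: str = "frobenius") -> CorrelationComparison:
    """Label-permutation test of correlation-matrix equality.

    The null pools all rows and reassigns group labels uniformly at random;
    the statistic is recomputed per permutation.  Reproducible from ``seed``.
    """
    xa, xb = _to_matrix(group_a), _to_matrix(group_b)
    if xa.shape[0] < 3 or xb.shape[0] < 3:
        raise InsufficientDataError("each group needs n >= 3 rows")
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("groups must share the column set")
    corr_a, corr_b = pearson_matrix(xa), pearson_matrix(xb)
    diff = correlation_difference(corr_a, corr_b)
    observed = _statistic(diff, statistic)
    pooled = np.vstack([xa, xb])
    n_a = xa.shape[0]
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        pa = _fast_corr(pooled[perm[:n_a]])
        pb = _fast_corr(pooled[perm[n_a:]])
        if _statistic(pa - pb, statistic) >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return CorrelationComparison(corr_a, corr_b, diff, observed, p, n_perm,
                                 statistic)
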