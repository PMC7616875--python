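"""Bivariate spatial correlation of maps: Lee's L, Moran's I, permutation tests.

Lee's L integrates Pearson's correlation with Moran-type spatial smoothing.
For centred vectors x, y and a spatial weight matrix V with row sums
``r_i = sum_j v_ij``::

    L = n / sum_i(r_i^2) * sum_i[(V x)_i (V y)_i] / (||x|| * ||y||)

so with self-only identity weights the spatial lag is the value itself and
L reduces exactly to Pearson's r. Moran's I is the univariate special case
with the cross-product of a vector against its own lag.

Significance is assessed by Monte-Carlo permutation: node values are
randomly reassigned to locations, which destroys spatial arrangement. The
default bivariate scheme permutes the (x, y) pairs jointly, preserving
their aspatial correlation, so the test isolates spatial co-patterning.
Two-tailed p-values double the smaller one-sided tail (ties counted as
exceedances) and are capped at 1; with M permutations the smallest
attainable p is 2/(M+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pgsmap.errors import (
    AlignmentError,
    DegenerateWeightsError,
    TransformError,
    ZeroVarianceError,
)
from pgsmap.grid import AnalysisGrid

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialWeightMatrix",
    "LeeTestResult",
    "contiguity_weights",
    "lee_statistic",
    "moran_i",
    "lee_permutation_test",
    "compare_maps",
    "env_transform",
    "bonferroni_flag",
]


@dataclass
class SpatialWeightMatrix:
    """Dense n-by-n non-negative spatial weights with zero diagonal."""

    matrix: np.ndarray
    row_standardized: bool = False

    def __post_init__(self):
        V = np.asarray(self.matrix, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(V < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(V) != 0):
            raise ValueError("weight matrix must have a zero diagonal")
        self.matrix = V

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def row_standardize(self) -> "SpatialWeightMatrix":
        """Scale each nonzero row to sum to one; zero rows stay zero."""
        sums = self.matrix.sum(axis=1, keepdims=True)
        safe = np.where(sums > 0, sums, 1.0)
        return SpatialWeightMatrix(self.matrix / safe, row_standardized=True)


@dataclass
class LeeTestResult:
    """Observed Lee's L with its Monte-Carlo permutation summary."""

    L_obs: float
    permutations: int
    p_two_tailed: float
    perm_mean: float
    perm_sd: float
    seed: int
    scheme: str = "joint"

    def __repr__(self):
        return (
            f"LeeTestResult(L={self.L_obs:.4f}, M={self.permutations}, "
            f"p={self.p_two_tailed:.4g})"
        )


def contiguity_weights(grid: AnalysisGrid, row_standardize: bool = True) -> SpatialWeightMatrix:
    """First-order hex-edge contiguity weights for a grid: 1 for nodes
    sharing a hexagon edge, 0 otherwise, optionally row-standardized."""
    n = grid.n_nodes
    V = np.zeros((n, n))
    for i, nbrs in enumerate(grid.adjacency):
        V[i, nbrs] = 1.0
    isolated = np.flatnonzero(V.sum(axis=1) == 0)
    if isolated.size:
        logger.warning("grid has %d isolated node(s): %s", isolated.size, isolated[:10])
    W = SpatialWeightMatrix(V)
    return W.row_standardize() if row_standardize else W


def _validate_pair(x, y, W: SpatialWeightMatrix):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = W.n
    if len(x) != n or len(y) != n:
        raise ValueError(f"x, y must have length {n} to match W")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("x and y must both be non-constant")
    if not W.matrix.any():
        raise DegenerateWeightsError("all spatial weights are zero")
    return x, y


def lee_statistic(x, y, W: SpatialWeightMatrix) -> float:
    """Lee's L bivariate spatial correlation of x and y under weights W.

    Symmetric in (x, y); with row-standardized contiguity weights it lies in
    [-1, 1] and measures how strongly the two surfaces co-pattern in space.
    """
    x, y = _validate_pair(x, y, W)
    V = W.matrix
    xc = x - x.mean()
    yc = y - y.mean()
    rows = V.sum(axis=1)
    denom = np.sqrt(xc @ xc) * np.sqrt(yc @ yc)
    return float(len(x) / (rows @ rows) * ((V @ xc) @ (V @ yc)) / denom)


def moran_i(x, W: SpatialWeightMatrix) -> float:
    """Global Moran's I spatial autocorrelation of x under weights W."""
    x, _ = _validate_pair(x, x, W)
    V = W.matrix
    xc = x - x.mean()
    s0 = V.sum()
    return float(len(x) / s0 * (xc @ (V @ xc)) / (xc @ xc))


def _lee_many(Xp: np.ndarray, Yp: np.ndarray, V: np.ndarray, rows2: float) -> np.ndarray:
    """Lee's L column-wise for matched (n, M) column stacks."""
    Xc = Xp - Xp.mean(axis=0)
    Yc = Yp - Yp.mean(axis=0)
    LX = V @ Xc
    LY = V @ Yc
    num = np.einsum("im,im->m", LX, LY)
    denom = np.sqrt(np.einsum("im,im->m", Xc, Xc) * np.einsum("im,im->m", Yc, Yc))
    return Xp.shape[0] / rows2 * num / denom


def lee_permutation_test(
    x, y, W: SpatialWeightMatrix, M: int = 10_000, seed: int = 0, scheme: str = "joint"
) -> LeeTestResult:
    """Monte-Carlo permutation test of Lee's L.

    Parameters
    ----------
    M : number of permutations (>= 99).
    scheme : ``"joint"`` permutes (x, y) pairs together across locations,
        preserving their aspatial correlation while destroying spatial
        arrangement (the default); ``"single"`` permutes y alone, which also
        breaks the aspatial pairing.

    The two-tailed p-value is ``2 * min(P[L* >= L_obs], P[L* <= L_obs])``
    with each tail estimated as ``(1 + count) / (M + 1)``, capped at 1;
    ties count as exceedances. Deterministic under ``seed``.
    """
    if M < 99:
        raise ValueError("M must be at least 99")
    if scheme not in ("joint", "single"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    x, y = _validate_pair(x, y, W)
    L_obs = lee_statistic(x, y, W)
    V = W.matrix
    rows = V.sum(axis=1)
    rows2 = float(rows @ rows)
    rng = np.random.default_rng(seed)
    n = len(x)
    perms = np.argsort(rng.random((M, n)), axis=1)  # M independent permutations
    Xp = x[perms].T if scheme == "joint" else np.tile(x[:, None], (1, M))
    Yp = y[perms].T
    L_perm = _lee_many(Xp, Yp, V, rows2)
    hi = (1 + int(np.sum(L_perm >= L_obs))) / (M + 1)
    lo = (1 + int(np.sum(L_perm <= L_obs))) / (M + 1)
    p = min(1.0, 2.0 * min(hi, lo))
    return LeeTestResult(
        L_obs=L_obs,
        permutations=M,
        p_two_tailed=p,
        perm_mean=float(L_perm.mean()),
        perm_sd=float(L_perm.std(ddof=1)),
        seed=seed,
        scheme=scheme,
    )


def _extract_values(m, transform: str) -> tuple[np.ndarray, pd.Index]:
    """Pull the node-indexed value vector out of a map-like object."""
    if hasattr(m, "table"):  # LocalFitMap
        tab = m.table
        vals, idx = tab["beta"], tab.index
    elif isinstance(m, pd.Series):
        vals, idx = m, m.index
    elif isinstance(m, pd.DataFrame):
        col = "beta" if "beta" in m.columns else "value"
        if col not in m.columns:
            raise AlignmentError("map table needs a 'beta' or 'value' column")
        vals, idx = m[col], m.index
    else:
        v = np.asarray(m, dtype=float)
        vals, idx = pd.Series(v), pd.RangeIndex(len(v))
    return env_transform(np.asarray(vals, dtype=float), transform), pd.Index(idx)


def compare_maps(
    map_a,
    map_b,
    W: SpatialWeightMatrix,
    M: int = 10_000,
    seed: int = 0,
    transform_a: str = "identity",
    transform_b: str = "identity",
    scheme: str = "joint",
) -> LeeTestResult:
    """Lee permutation test between two node-aligned maps.

    Maps may be :class:`~pgsmap.local.LocalFitMap` objects (the beta surface
    is used), node-indexed Series/DataFrames, or plain arrays. Both must be
    aligned on the same grid node index.
    """
    a, idx_a = _extract_values(map_a, transform_a)
    b, idx_b = _extract_values(map_b, transform_b)
    if len(idx_a) != len(idx_b) or not idx_a.equals(idx_b):
        unmatched = idx_a.symmetric_difference(idx_b)
        raise AlignmentError(
            f"maps are not aligned on the same node index; {len(unmatched)} unmatched: "
            f"{list(unmatched[:10])}"
        )
    res = lee_permutation_test(a, b, W, M=M, seed=seed, scheme=scheme)
    return res


def env_transform(values, kind: str = "identity") -> np.ndarray:
    """Apply the stated transform to environmental values before comparison.

    ``log`` takes natural logs (positively skewed measures such as
    population density and deprivation indices); ``identity`` passes
    through.
    """
    v = np.asarray(values, dtype=float)
    if kind == "identity":
        return v
    if kind == "log":
        bad = np.flatnonzero(v <= 0)
        if bad.size:
            raise TransformError(f"log transform needs positive values; offending nodes: {bad[:20].tolist()}")
        return np.log(v)
    raise TransformError(f"unknown transform {kind!r}")


def bonferroni_flag(p_values, alpha: float = 0.05, k: int = 1) -> np.ndarray:
    """Strong-evidence flags under a Bonferroni correction for k tests.

    ``flag = p < alpha / k``; with the conventional 15 environment-by-trait
    comparisons the working threshold is 0.05/15 ~ 0.0033.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return np.asarray(p_values, dtype=float) < alpha / k
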