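"""Local weighted regression: the genetic-influence maps.

At every grid node a weighted least-squares regression of the trait on the
polygenic score plus covariates is fitted, with participant weights from the
inverse-distance kernel. The PGS coefficient at a node is the local
"genetic influence": the change in trait per SD of PGS for participants
near that location.

Standard errors are classical WLS standard errors treating the kernel
weights as precision weights. The source study reports no per-node
uncertainty, so any internally consistent convention is admissible; the
convention used here is recorded in the map metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pgsmap.errors import DimensionError, EmptyMapError, SingularDesignError
from pgsmap.grid import AnalysisGrid
from pgsmap.kernel import WeightKernel

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "LocalFitMap", "fit_weighted_model", "map_associations"]


@dataclass(frozen=True)
class ModelSpec:
    """Column bindings for the local regression model.

    ``trait ~ intercept + pgs + covariates``. Sex is always a covariate;
    age is included unless the trait is a cross-age composite; optional
    ancestry principal-component columns pass through unchanged.
    """

    trait: str
    pgs: str
    covariates: tuple[str, ...] = ("sex", "age")

    def __post_init__(self):
        if self.trait == self.pgs:
            raise ValueError("trait and pgs columns must be distinct")
        if self.trait in self.covariates or self.pgs in self.covariates:
            raise ValueError("covariates must exclude the trait and pgs columns")

    @property
    def design_columns(self) -> list[str]:
        return [self.pgs, *self.covariates]


@dataclass
class LocalFitMap:
    """Per-node regression output for one PGS threshold.

    ``table`` has one row per grid node: node index, coordinates, the PGS
    coefficient ``beta``, its standard error ``se``, the effective number of
    contributing participants ``n_effective = (sum w)^2 / sum w^2``, and a
    ``converged`` flag. Metadata records the model and kernel used.
    """

    table: pd.DataFrame
    model: ModelSpec
    kernel: WeightKernel
    meta: dict = field(default_factory=dict)

    @property
    def beta(self) -> np.ndarray:
        return self.table["beta"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


def _design(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in [spec.trait, *spec.design_columns] if c not in df.columns]
    if missing:
        raise DimensionError(f"cohort is missing model columns: {missing}")
    y = df[spec.trait].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(df)), *(df[c].to_numpy(dtype=float) for c in spec.design_columns)]
    )
    return X, y


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns implicated: those whose removal restores full rank
        collinear = []
        for k in range(1, X.shape[1]):
            Xk = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(Xk) == rank:
                collinear.append(names[k - 1])
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear columns: {collinear or names}"
        )


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form WLS: beta = (X'WX)^-1 X'Wy, classical precision-weight SEs."""
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    XtWy = Xw.T @ y
    beta = np.linalg.solve(XtWX, XtWy)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(w @ resid**2) / dof
    cov = sigma2 * np.linalg.inv(XtWX)
    return beta, np.sqrt(np.diag(cov)), resid


def fit_weighted_model(cohort_rows: pd.DataFrame, model_spec: ModelSpec, weights) -> pd.DataFrame:
    """Weighted least squares with intercept for one analysis location.

    Returns a table with one row per coefficient (``const``, the PGS, then
    covariates): the point estimate and its standard error. Weights are
    precision weights; rescaling them by any positive constant leaves both
    estimates and standard errors unchanged.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(cohort_rows):
        raise DimensionError(f"{len(w)} weights for {len(cohort_rows)} rows")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    X, y = _design(cohort_rows, model_spec)
    if X.shape[0] < X.shape[1] + 2:
        raise DimensionError(
            f"need at least {X.shape[1] + 2} rows for {X.shape[1]} coefficients, got {X.shape[0]}"
        )
    _check_rank(X, model_spec.design_columns)
    beta, se, _ = _wls(X, y, w)
    return pd.DataFrame(
        {"coef": beta, "se": se}, index=["const", *model_spec.design_columns]
    )


def map_associations(
    cohort: pd.DataFrame,
    grid: AnalysisGrid,
    kernel: WeightKernel,
    model_spec: ModelSpec,
    coord_columns: tuple[str, str] = ("x", "y"),
) -> LocalFitMap:
    """Fit the weighted model at every grid node.

    Participants with missing trait, covariate, PGS or coordinate values are
    dropped once, globally (complete-case), before any node is fitted. Nodes
    where the fit fails are flagged ``converged=False``, never dropped.
    """
    cols = [model_spec.trait, *model_spec.design_columns, *coord_columns]
    data = cohort.dropna(subset=cols)
    n_dropped = len(cohort) - len(data)
    if n_dropped:
        logger.info("dropped %d incomplete rows; %d analysed", n_dropped, len(data))
    X, y = _design(data, model_spec)
    _check_rank(X, model_spec.design_columns)
    coords = data[list(coord_columns)].to_numpy(dtype=float)
    nodes = grid.nodes
    k = X.shape[1]

    # all node-participant distances, then batched normal equations per node
    d = np.hypot(
        nodes[:, 0:1] - coords[None, :, 0], nodes[:, 1:2] - coords[None, :, 1]
    )
    W = 1.0 / np.maximum(d, kernel.min_distance) ** kernel.power  # (n_nodes, n)

    XtWX = np.einsum("np,pi,pj->nij", W, X, X, optimize=True)
    XtWy = np.einsum("np,pi,p->ni", W, X, y, optimize=True)
    out = np.full((len(nodes), 3), np.nan)
    converged = np.zeros(len(nodes), dtype=bool)
    dof = X.shape[0] - k
    pgs_idx = 1  # column order: const, pgs, covariates
    for i in range(len(nodes)):
        try:
            beta = np.linalg.solve(XtWX[i], XtWy[i])
        except np.linalg.LinAlgError:
            logger.warning("node %d: singular local design, flagged not converged", i)
            continue
        resid = y - X @ beta
        w = W[i]
        sigma2 = float(w @ resid**2) / dof
        cov_pgs = sigma2 * np.linalg.inv(XtWX[i])[pgs_idx, pgs_idx]
        if not np.isfinite(beta[pgs_idx]) or cov_pgs <= 0:
            continue
        sw = w.sum()
        out[i] = (beta[pgs_idx], np.sqrt(cov_pgs), sw * sw / float(w @ w))
        converged[i] = True
    if not converged.any():
        raise EmptyMapError("fitting failed at every grid node")
    logger.info("fitted %d/%d nodes", int(converged.sum()), len(nodes))
    table = pd.DataFrame(
        {
            "node": np.arange(len(nodes)),
            "x": nodes[:, 0],
            "y": nodes[:, 1],
            "beta": out[:, 0],
            "se": out[:, 1],
            "n_effective": out[:, 2],
            "converged": converged,
        }
    ).set_index("node")
    meta = {
        "n_analysed": len(data),
        "n_dropped": n_dropped,
        "se_convention": "classical WLS, weights as precision weights",
        "kernel_power": kernel.power,
        "kernel_min_distance": kernel.min_distance,
    }
    return LocalFitMap(table=table, model=model_spec, kernel=kernel, meta=meta)
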