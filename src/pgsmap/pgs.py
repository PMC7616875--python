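"""Polygenic score construction by p-value thresholding.

A participant's raw score at threshold t is the sum of risk-allele dosages
(0, 1 or 2) over the SNPs with discovery-GWAS p-value strictly below t,
each weighted by the discovery effect size. Scores are z-standardized over
the analysed sample, so downstream coefficients are on the scale of trait
change per SD of PGS. The best threshold is the one whose unweighted,
covariate-adjusted linear model explains the most trait variance by
adjusted R².

Dosages are assumed pre-aligned to the GWAS effect allele; for real data a
strand/allele reconciliation step is provided (flip swapped alleles, drop
strand-ambiguous A/T and C/G SNPs). SNPs are scored independently — LD
clumping is not performed, but a pre-clumped SNP list can be supplied to
restrict scoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from pgsmap.errors import ConfigError, EmptyScoreError, ZeroVarianceError

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSet",
    "score_participants",
    "standardize",
    "build_pgs_matrix",
    "select_best_threshold",
    "reconcile_alleles",
    "pgs_column_name",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered p-value thresholds at which scores are built.

    The default set spans genome-wide significance to near-agnostic
    inclusion: 5e-8, 1e-5 and 0.5.
    """

    thresholds: tuple[float, ...] = (5e-8, 1e-5, 0.5)

    def __post_init__(self):
        t = tuple(self.thresholds)
        if not t:
            raise ConfigError("threshold set must be nonempty")
        if any(not (0 < x <= 1) for x in t):
            raise ConfigError("thresholds must lie in (0, 1]")
        if any(a >= b for a, b in zip(t, t[1:])):
            raise ConfigError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", t)

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self):
        return len(self.thresholds)


def pgs_column_name(threshold: float) -> str:
    """Canonical cohort column name for a threshold, e.g. ``pgs_5e-08``."""
    return f"pgs_{threshold:g}"


def _validate_gwas(gwas: pd.DataFrame) -> pd.DataFrame:
    for col in ("snp", "beta", "p"):
        if col not in gwas.columns:
            raise ConfigError(f"GWAS summary statistics need a {col!r} column")
    if gwas["snp"].duplicated().any():
        dupes = gwas.loc[gwas["snp"].duplicated(), "snp"].unique()
        raise ConfigError(f"duplicate SNP ids in GWAS summary statistics: {dupes[:5]}")
    p = gwas["p"].to_numpy(dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ConfigError("GWAS p-values must lie in (0, 1]")
    if np.any(~np.isfinite(gwas["beta"].to_numpy(dtype=float))):
        raise ConfigError("GWAS effect sizes must be finite")
    return gwas


def score_participants(
    dosages: pd.DataFrame,
    gwas: pd.DataFrame,
    threshold: float,
    snp_subset: list[str] | None = None,
) -> pd.Series:
    """Raw weighted allele-count scores at one p-value threshold.

    Parameters
    ----------
    dosages : participants x SNPs dosage matrix (values 0/1/2), columns
        named by SNP id, aligned to the GWAS effect allele.
    gwas : summary statistics with columns ``snp``, ``beta``, ``p``.
    threshold : include SNPs with ``p < threshold`` (strict).
    snp_subset : optional pre-clumped SNP list restricting scoring.

    Returns
    -------
    Series of raw scores indexed like ``dosages``; SNPs absent from either
    side are dropped with a logged count.
    """
    if not (0 < threshold <= 1):
        raise ConfigError(f"threshold must be in (0, 1], got {threshold}")
    gwas = _validate_gwas(gwas)
    sel = gwas[gwas["p"].to_numpy(dtype=float) < threshold]
    if snp_subset is not None:
        sel = sel[sel["snp"].isin(snp_subset)]
    passing = sel["snp"].tolist()
    usable = [s for s in passing if s in dosages.columns]
    n_dropped = len(passing) - len(usable)
    if n_dropped:
        logger.info(
            "threshold %g: %d SNP(s) passing but absent from dosages, dropped",
            threshold,
            n_dropped,
        )
    if not usable:
        raise EmptyScoreError(f"no SNP passes threshold p < {threshold:g}")
    betas = sel.set_index("snp").loc[usable, "beta"].to_numpy(dtype=float)
    return pd.Series(
        dosages[usable].to_numpy(dtype=float) @ betas, index=dosages.index, name="raw_score"
    )


def standardize(raw_scores) -> np.ndarray:
    """z-scores: (x - mean) / SD with the n-1 sample standard deviation."""
    x = np.asarray(raw_scores, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ZeroVarianceError("cannot standardize a constant score vector")
    return (x - x.mean()) / sd


def build_pgs_matrix(
    dosages: pd.DataFrame, gwas: pd.DataFrame, thresholds: ThresholdSet | None = None
) -> pd.DataFrame:
    """z-standardized PGS at every threshold, one column per threshold."""
    thresholds = thresholds or ThresholdSet()
    cols = {}
    for t in thresholds:
        raw = score_participants(dosages, gwas, t)
        cols[pgs_column_name(t)] = standardize(raw)
    return pd.DataFrame(cols, index=dosages.index)


def reconcile_alleles(gwas: pd.DataFrame, genotype_alleles: pd.DataFrame) -> pd.DataFrame:
    """Align GWAS effect alleles to the genotype coding for real data.

    ``genotype_alleles`` has columns ``snp``, ``counted``, ``other``: the
    allele whose dosage is counted and the alternative. Matching alleles
    pass through; swapped alleles have the effect sign flipped; strand flips
    are resolved by complementing; strand-ambiguous A/T and C/G SNPs are
    dropped, as are SNPs whose alleles cannot be reconciled.
    """
    gwas = _validate_gwas(gwas)
    if "effect_allele" not in gwas.columns:
        raise ConfigError("GWAS table needs an effect_allele column to reconcile")
    merged = gwas.merge(genotype_alleles, on="snp", how="inner")
    keep, betas = [], []
    n_ambig = n_unmatched = 0
    for row in merged.itertuples(index=False):
        ea, counted, other = row.effect_allele, row.counted, row.other
        if (counted, other) in AMBIGUOUS_PAIRS:
            n_ambig += 1
            continue
        if ea == counted:
            flip = False
        elif ea == other:
            flip = True
        elif COMPLEMENT.get(ea) == counted:
            flip = False
        elif COMPLEMENT.get(ea) == other:
            flip = True
        else:
            n_unmatched += 1
            continue
        keep.append(row.snp)
        betas.append(-row.beta if flip else row.beta)
    if n_ambig or n_unmatched:
        logger.info(
            "allele reconciliation dropped %d ambiguous and %d unmatched SNP(s)",
            n_ambig,
            n_unmatched,
        )
    out = gwas[gwas["snp"].isin(keep)].copy()
    out["beta"] = out["snp"].map(dict(zip(keep, betas)))
    return out.reset_index(drop=True)


def _adjusted_r2(r2: float, n: int, k: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def select_best_threshold(
    cohort: pd.DataFrame,
    thresholds: ThresholdSet,
    model_spec,
) -> tuple[float, pd.DataFrame]:
    """Pick the threshold whose unweighted model explains most variance.

    Fits ``trait ~ pgs_t + covariates`` by ordinary (unweighted) least
    squares for every threshold with a score column present in ``cohort``
    and returns the adjusted-R² argmax together with the per-threshold fit
    table (n, R², adjusted R², and the incremental ΔR² over a
    covariates-only baseline). Ties within 1e-12 break toward the smaller,
    more stringent threshold with a warning. When every ΔR² is negligible
    the table's ``null_signal`` flag marks all rows.
    """
    rows = []
    cols = [model_spec.trait, *model_spec.covariates]
    have = [t for t in thresholds if pgs_column_name(t) in cohort.columns]
    if not have:
        raise ConfigError("cohort has no PGS column for any requested threshold")
    for t in have:
        pgs_col = pgs_column_name(t)
        data = cohort.dropna(subset=cols + [pgs_col])
        y = data[model_spec.trait].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ZeroVarianceError("trait is constant; cannot select a threshold")
        X = sm.add_constant(data[[pgs_col, *model_spec.covariates]].to_numpy(dtype=float))
        fit = sm.OLS(y, X).fit()
        X0 = sm.add_constant(data[list(model_spec.covariates)].to_numpy(dtype=float))
        fit0 = sm.OLS(y, X0).fit()
        rows.append(
            {
                "threshold": t,
                "n": int(fit.nobs),
                "r2": fit.rsquared,
                "adj_r2": fit.rsquared_adj,
                "delta_r2": fit.rsquared - fit0.rsquared,
            }
        )
    table = pd.DataFrame(rows)
    best_val = table["adj_r2"].max()
    tied = table[table["adj_r2"] >= best_val - 1e-12]
    if len(tied) > 1:
        warnings.warn(
            "adjusted R² tie across thresholds; choosing the most stringent",
            stacklevel=2,
        )
    best = float(tied["threshold"].min())
    table["selected"] = table["threshold"] == best
    # chance-level incremental R2 for one added regressor is ~ chi2(1)/n
    # (99.8th percentile ~ 10/n): flag when no threshold clears it
    table["null_signal"] = bool(
        (table["delta_r2"] < 10.0 / table["n"]).all()
    )
    return best, table
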