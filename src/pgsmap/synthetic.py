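"""Synthetic geo-clustered cohorts with a planted spatial genetic effect.

Real cohort data of this kind is managed-access, so the generator emulates
its structure: children clustered around a city region (Gaussian settlement
clusters truncated to the study polygon), independent SNP genotypes with a
discovery-GWAS summary table, a trait generated as

    y_i = alpha + beta(s_i) * G_i + gamma_sex * sex_i + gamma_age * age_i + eps_i

where ``G_i`` is the standardized true genetic score of participant i and
``beta(s)`` is a configurable surface (constant, linear gradient, or radial
bump) over planar coordinates — the ground truth every downstream map
estimator is checked against. Environmental surfaces are generated at grid
nodes as transforms of Gaussian fields mixed with the beta surface at a
controlled correlation, and an optional logistic attrition model thins the
cohort as a function of PGS.

All coordinates are planar metres; every operation is deterministic given
the configuration seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm
from shapely.geometry import Point, Polygon

from pgsmap.errors import ConfigError, DimensionError, InvalidRegionError
from pgsmap.grid import AnalysisGrid, as_polygon
from pgsmap.pgs import ThresholdSet, build_pgs_matrix, pgs_column_name, standardize

__all__ = [
    "ConstantBeta",
    "LinearGradientBeta",
    "RadialBeta",
    "EnvSurfaceSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedStudy",
    "simulate_locations",
    "simulate_genotypes_and_gwas",
    "simulate_traits",
    "simulate_env_surfaces",
    "apply_attrition",
    "simulate_cohort",
]


# ---------------------------------------------------------------- beta surfaces
@dataclass(frozen=True)
class ConstantBeta:
    """Spatially uniform true effect."""

    c: float = 0.1

    def at(self, xy) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return np.full(len(xy), self.c)


@dataclass(frozen=True)
class LinearGradientBeta:
    """Planar gradient ``beta(x, y) = b0 + bx*x + by*y`` (slopes per metre)."""

    b0: float = 0.0
    bx: float = 0.0
    by: float = 0.0

    def at(self, xy) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return self.b0 + self.bx * xy[:, 0] + self.by * xy[:, 1]


@dataclass(frozen=True)
class RadialBeta:
    """Gaussian bump: ``baseline + amplitude * exp(-d^2 / (2*scale^2))``
    with d the distance to ``centre``."""

    centre: tuple[float, float]
    scale: float
    amplitude: float = 0.2
    baseline: float = 0.0

    def at(self, xy) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d2 = (xy[:, 0] - self.centre[0]) ** 2 + (xy[:, 1] - self.centre[1]) ** 2
        return self.baseline + self.amplitude * np.exp(-d2 / (2.0 * self.scale**2))


@dataclass(frozen=True)
class EnvSurfaceSpec:
    """One environmental surface: name, value transform, and the target
    correlation of its latent field with the true beta surface."""

    name: str
    transform: str = "identity"  # identity | lognormal | categorical3
    rho: float = 0.0

    def __post_init__(self):
        if self.transform not in ("identity", "lognormal", "categorical3"):
            raise ConfigError(f"unknown env transform {self.transform!r}")
        if not -1.0 <= self.rho <= 1.0:
            raise ConfigError("env surface correlation rho must lie in [-1, 1]")


DEFAULT_ENV_SPECS = (
    EnvSurfaceSpec("population_density", "lognormal", -0.3),
    EnvSurfaceSpec("qualification_level", "identity", 0.3),
    EnvSurfaceSpec("imd", "lognormal", -0.3),
    EnvSurfaceSpec("urbanicity", "categorical3", -0.3),
    EnvSurfaceSpec("sunshine_hours", "identity", 0.5),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; defaults emulate a city-region birth
    cohort of mid-childhood children.

    Key fields
    ----------
    n_participants : cohort size (default 5000, within the 4000-8000 band
        typical of complete-case analyses in such cohorts).
    region : study polygon or (xmin, ymin, xmax, ymax) rectangle in metres;
        default a 40 km x 30 km rectangle.
    n_clusters, cluster_sd : settlement centres and their Gaussian spread.
    n_snps, effect_fraction : independent SNPs and the fraction carrying a
        true effect.
    beta_surface : the planted spatially varying PGS-to-trait coefficient.
    trait_noise_sd : residual SD of the trait.
    sex_effect, age_effect : covariate coefficients in the trait model.
    env_surfaces : environmental surface specs (two log-skewed, one smooth
        continuous, one ordinal-continuous, one 3-level categorical by
        default, mirroring population density, qualification level,
        deprivation, urbanicity and sunshine).
    attrition_gamma : log-odds of retention per SD of PGS (0 = no attrition).
    attrition_target_rate : expected retention fraction in (0, 1].
    """

    n_participants: int = 5000
    region: object = (0.0, 0.0, 40_000.0, 30_000.0)
    n_clusters: int = 8
    cluster_sd: float = 2500.0
    cluster_weights: tuple[float, ...] | None = None
    n_snps: int = 200
    effect_fraction: float = 0.1
    effect_sd: float = 0.05
    snp_effects: tuple[float, ...] | None = None  # overrides the random draw
    gwas_n: int = 50_000
    beta_surface: object = field(default_factory=ConstantBeta)
    intercept: float = 0.0
    trait_noise_sd: float = 1.0
    sex_effect: float = 0.25
    age_effect: float = 0.1
    age_mean: float = 10.7
    age_sd: float = 0.12
    env_surfaces: tuple[EnvSurfaceSpec, ...] = DEFAULT_ENV_SPECS
    attrition_gamma: float = 0.0
    attrition_target_rate: float = 1.0
    env_noise_smoothing: int = 0  # neighbourhood-averaging passes on env noise
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    use_genotypes: bool = True
    trait_scale: tuple[int, int] | None = None  # e.g. (0, 10); off by default
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 50:
            raise ConfigError("n_participants must be at least 50")
        if self.cluster_sd <= 0:
            raise ConfigError("cluster_sd must be positive")
        if self.trait_noise_sd <= 0:
            raise ConfigError("trait_noise_sd must be positive")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ConfigError("effect_fraction must lie in [0, 1]")
        if not 0.0 < self.attrition_target_rate <= 1.0:
            raise ConfigError("attrition_target_rate must lie in (0, 1]")
        if not math.isfinite(self.attrition_gamma):
            raise ConfigError("attrition_gamma must be finite")
        if self.cluster_weights is not None:
            w = np.asarray(self.cluster_weights, dtype=float)
            if len(w) != self.n_clusters or np.any(w < 0) or w.sum() <= 0:
                raise ConfigError("cluster_weights must be n_clusters non-negative values")

    def polygon(self) -> Polygon:
        return as_polygon(self.region)

    def weights(self) -> np.ndarray:
        if self.cluster_weights is None:
            return np.full(self.n_clusters, 1.0 / self.n_clusters)
        w = np.asarray(self.cluster_weights, dtype=float)
        return w / w.sum()


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study."""

    config: SimulationConfig
    cluster_centres: np.ndarray
    cluster_assignment: np.ndarray
    true_effects: np.ndarray | None = None
    true_score: np.ndarray | None = None
    env_truth: dict = field(default_factory=dict)
    retained_ids: np.ndarray | None = None

    def beta_at(self, locations) -> np.ndarray:
        """True local PGS-to-trait coefficient at planar locations;
        deterministic given the configuration."""
        return self.config.beta_surface.at(locations)


@dataclass
class SimulatedStudy:
    """Bundle returned by :func:`simulate_cohort`."""

    cohort: pd.DataFrame
    genotypes: pd.DataFrame | None
    gwas: pd.DataFrame | None
    truth: SyntheticTruth
    config: SimulationConfig


def _rng_for(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible substream per operation (crc32 keys the
    stream name: unlike ``hash``, it is stable across processes)."""
    key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


def _draw_centres(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    poly = config.polygon()
    xmin, ymin, xmax, ymax = poly.bounds
    centres = []
    for _ in range(100_000):
        if len(centres) == config.n_clusters:
            break
        p = (rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
        if poly.contains(Point(p)):
            centres.append(p)
    else:
        raise InvalidRegionError("could not place cluster centres inside region")
    return np.asarray(centres)


def simulate_locations(config: SimulationConfig) -> tuple[np.ndarray, SyntheticTruth]:
    """Participant residence coordinates: a Gaussian mixture over settlement
    centres, truncated to the study region by resampling the offset (so the
    mixture proportions are preserved exactly)."""
    poly = config.polygon()
    rng = _rng_for(config, "locations")
    centres = _draw_centres(config, rng)
    comp = rng.choice(config.n_clusters, size=config.n_participants, p=config.weights())
    pts = np.empty((config.n_participants, 2))
    for i, c in enumerate(comp):
        for _ in range(10_000):
            p = centres[c] + rng.normal(scale=config.cluster_sd, size=2)
            if poly.contains(Point(p)):
                pts[i] = p
                break
        else:  # pathologically tight region: fall back to the centre itself
            pts[i] = centres[c]
    truth = SyntheticTruth(config=config, cluster_centres=centres, cluster_assignment=comp)
    return pts, truth


def simulate_genotypes_and_gwas(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Independent SNP dosages plus a discovery-GWAS summary table.

    Dosages are Binomial(2, MAF) with MAF ~ Uniform(0.05, 0.5). A fraction
    ``effect_fraction`` of SNPs carries a true effect ~ N(0, effect_sd²)
    (or the effects are taken verbatim from ``config.snp_effects``); the
    summary table reports that effect, the effect-allele frequency, and a
    p-value from a simulated discovery z-statistic
    ``z = beta * sqrt(2*maf*(1-maf)*gwas_n) + N(0,1)``, so p decreases in
    |effect| and is Uniform(0,1] for null SNPs.

    Returns (dosages, gwas, true_effects).
    """
    if config.n_snps < 1:
        raise ConfigError("n_snps must be at least 1")
    rng = _rng_for(config, "genotypes")
    m, n = config.n_snps, config.n_participants
    maf = rng.uniform(0.05, 0.5, size=m)
    dosages = rng.binomial(2, maf[None, :], size=(n, m)).astype(np.int8)
    if config.snp_effects is not None:
        effects = np.asarray(config.snp_effects, dtype=float)
        if len(effects) != m:
            raise ConfigError(f"snp_effects must have length n_snps={m}")
    else:
        effects = np.zeros(m)
        n_causal = int(round(config.effect_fraction * m))
        causal = rng.choice(m, size=n_causal, replace=False)
        effects[causal] = rng.normal(scale=config.effect_sd, size=n_causal)
    z = effects * np.sqrt(2.0 * maf * (1.0 - maf) * config.gwas_n) + rng.normal(size=m)
    p = np.clip(2.0 * norm.sf(np.abs(z)), 1e-300, 1.0)
    snp_ids = [f"snp_{j:05d}" for j in range(m)]
    alleles = rng.choice(list("ACGT"), size=m)
    dos = pd.DataFrame(dosages, columns=snp_ids)
    gwas = pd.DataFrame(
        {"snp": snp_ids, "effect_allele": alleles, "beta": effects, "freq": maf, "p": p}
    )
    return dos, gwas, effects


def simulate_traits(
    locations,
    pgs,
    covariates: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> np.ndarray:
    """Trait values from the planted local-effect model.

    ``y = intercept + beta(s)*pgs + sex_effect*sex + age_effect*age + eps``
    with ``eps ~ N(0, trait_noise_sd²)``. ``pgs`` should be standardized.
    An optional bounded-integer discretization (``config.trait_scale``)
    mimicking questionnaire total scores is off by default: the fitted model
    is linear either way.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    pgs = np.asarray(pgs, dtype=float)
    if not (len(locations) == len(pgs) == len(covariates)):
        raise DimensionError(
            f"length mismatch: {len(locations)} locations, {len(pgs)} scores, "
            f"{len(covariates)} covariate rows"
        )
    rng = _rng_for(config, "traits")
    beta = truth.beta_at(locations)
    y = (
        config.intercept
        + beta * pgs
        + config.sex_effect * covariates["sex"].to_numpy(dtype=float)
        + config.age_effect * covariates["age"].to_numpy(dtype=float)
        + rng.normal(scale=config.trait_noise_sd, size=len(pgs))
    )
    if config.trait_scale is not None:
        lo, hi = config.trait_scale
        # affine-map the bulk of the distribution onto the scale, then round
        span = y.max() - y.min()
        y = np.clip(np.round((y - y.min()) / (span or 1.0) * (hi - lo) + lo), lo, hi)
    return y


def _smooth_field(n: int, adjacency: list[list[int]], rng: np.random.Generator, passes: int = 0) -> np.ndarray:
    """Standard-normal field, optionally spatially smoothed by averaging
    with its neighbourhood ``passes`` times, then re-standardized."""
    g = rng.normal(size=n)
    for _ in range(passes):
        lag = np.array([g[nbrs].mean() if nbrs else g[i] for i, nbrs in enumerate(adjacency)])
        g = 0.5 * g + 0.5 * lag
    return standardize(g) if n > 1 else g


def simulate_env_surfaces(
    grid: AnalysisGrid, truth: SyntheticTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Environmental surface values at the grid nodes.

    Each surface's latent field is ``rho * z_beta + sqrt(1-rho²) * z_noise``
    where ``z_beta`` is the standardized true beta surface at the nodes and
    ``z_noise`` an independent Gaussian field (iid across nodes by default;
    ``config.env_noise_smoothing`` adds neighbourhood-averaging passes, at
    the cost of breaking the exchangeability null of the permutation tests
    for surfaces that are independent of the beta surface). The latent
    field then passes through the configured transform: ``identity`` (smooth continuous), ``lognormal``
    (positive, right-skewed, as for population density or deprivation
    scores), or ``categorical3`` (tercile levels 0/1/2, as for
    village/town/urban classifications). Surfaces are stored on
    ``truth.env_truth`` and returned as a node-indexed table.
    """
    if grid.n_nodes == 0:
        raise ConfigError("grid must be nonempty")
    rng = _rng_for(config, "environment")
    b = truth.beta_at(grid.nodes)
    if np.ptp(b) == 0:  # constant beta surface: correlate against pure noise
        z_b = _smooth_field(grid.n_nodes, grid.adjacency, rng)
    else:
        z_b = standardize(b)
    out = {}
    for spec in config.env_surfaces:
        z_e = _smooth_field(
            grid.n_nodes, grid.adjacency, rng, passes=config.env_noise_smoothing
        )
        latent = spec.rho * z_b + math.sqrt(1.0 - spec.rho**2) * z_e
        if spec.transform == "identity":
            vals = latent
        elif spec.transform == "lognormal":
            vals = np.exp(latent)
        else:  # categorical3
            terciles = np.quantile(latent, [1 / 3, 2 / 3])
            vals = np.digitize(latent, terciles).astype(float)
        out[spec.name] = vals
    table = pd.DataFrame(out, index=pd.RangeIndex(grid.n_nodes, name="node"))
    truth.env_truth.update({k: v.to_numpy() for k, v in table.items()})
    return table


def apply_attrition(pgs, config: SimulationConfig) -> np.ndarray:
    """Participant indices retained under PGS-linked logistic attrition.

    Retention probability is ``logistic(lambda0 + attrition_gamma * PGS)``
    with the intercept solved so the expected retention equals
    ``attrition_target_rate``.
    """
    pgs = np.asarray(pgs, dtype=float)
    rate = config.attrition_target_rate
    if config.attrition_gamma == 0.0 and rate == 1.0:
        return np.arange(len(pgs))
    if rate == 1.0:
        prob = np.ones(len(pgs))
    else:
        lam0 = brentq(lambda l0: expit(l0 + config.attrition_gamma * pgs).mean() - rate, -50, 50)
        prob = expit(lam0 + config.attrition_gamma * pgs)
    rng = _rng_for(config, "attrition")
    return np.flatnonzero(rng.random(len(pgs)) < prob)


def simulate_cohort(config: SimulationConfig) -> SimulatedStudy:
    """Full generative pipeline: locations, genotypes and GWAS, polygenic
    scores, covariates, trait, attrition.

    With ``use_genotypes=False`` the standardized true score is drawn
    directly as N(0,1) and exposed as a single ``pgs`` column — the fast
    path for method-level simulations that do not exercise score
    construction.
    """
    locations, truth = simulate_locations(config)
    rng = _rng_for(config, "covariates")
    sex = rng.integers(0, 2, size=config.n_participants)
    age = rng.normal(config.age_mean, config.age_sd, size=config.n_participants)
    covariates = pd.DataFrame({"sex": sex, "age": age})

    if config.use_genotypes:
        dosages, gwas, effects = simulate_genotypes_and_gwas(config)
        truth.true_effects = effects
        raw_true = dosages.to_numpy(dtype=float) @ effects
        if np.ptp(raw_true) == 0:  # no causal SNP: genetic value is pure noise
            true_score = _rng_for(config, "nullscore").normal(size=config.n_participants)
            true_score = standardize(true_score)
        else:
            true_score = standardize(raw_true)
        pgs_cols = build_pgs_matrix(dosages, gwas, config.thresholds)
    else:
        dosages = gwas = None
        true_score = standardize(_rng_for(config, "score").normal(size=config.n_participants))
        pgs_cols = pd.DataFrame({"pgs": true_score})
    truth.true_score = true_score

    trait = simulate_traits(locations, true_score, covariates, truth, config)
    cohort = pd.DataFrame(
        {
            "id": [f"P{i:06d}" for i in range(config.n_participants)],
            "x": locations[:, 0],
            "y": locations[:, 1],
            "trait": trait,
            "sex": sex,
            "age": age,
        }
    )
    cohort = pd.concat([cohort, pgs_cols], axis=1)

    attr_col = pgs_cols.columns[-1]  # attrition acts on the broadest score
    retained = apply_attrition(cohort[attr_col].to_numpy(), config)
    truth.retained_ids = cohort["id"].to_numpy()[retained]
    cohort = cohort.iloc[retained].reset_index(drop=True)
    return SimulatedStudy(cohort=cohort, genotypes=dosages, gwas=gwas, truth=truth, config=config)
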