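# pgsmap

Spatially weighted polygenic-score association mapping.

Population-level analyses of polygenic scores (PGS) report one regression
coefficient per trait — but the strength of a genetic association can vary
from place to place when local environments draw out or mask genetic
influences. `pgsmap` maps this variation at high spatial resolution within a
study region, and tests whether the resulting "genetic influence" surfaces
co-pattern with each other and with environmental surfaces. It is written
for epidemiologists and statistical geneticists working with geocoded
cohort data, and ships a full synthetic-study generator so every stage of
the pipeline can be validated against planted ground truth.

## The method

1. **Scores.** For each participant, a PGS at discovery p-value threshold
   *p<sub>T</sub>* is the weighted allele count
   `S_i = Σ_{j : p_j < pT} β_j · g_ij` over independent SNPs, z-standardized;
   the *p<sub>T</sub>* explaining the most trait variance (adjusted R² of an
   unweighted covariate-adjusted linear model) is selected alongside a
   fixed ladder (default 5×10⁻⁸, 1×10⁻⁵, .5).
2. **Maps.** A regular hexagonal grid is laid over the study polygon. At
   every grid node *x* a weighted least-squares regression
   `trait ~ PGS + sex + age` is fitted with inverse-distance participant
   weights `w_i(x) = 1 / d(x_i, x)^0.5`, so every participant contributes
   everywhere and nearby participants dominate. The node-wise PGS
   coefficient β(x) is the local genetic influence.
3. **Comparison.** Two node-valued surfaces are compared with Lee's L, a
   bivariate statistic integrating Pearson correlation with Moran-type
   spatial smoothing: with spatial weights `v_ij` and centred surfaces,
   `L = n/Σ_i(Σ_j v_ij)² · Σ_i (Σ_j v_ij x̃_j)(Σ_j v_ij ỹ_j) / (‖x̃‖‖ỹ‖)`.
   Significance comes from a Monte-Carlo permutation test (values
   reassigned across locations; two-tailed p by doubling the smaller tail,
   floor 2/(M+1)), with a Bonferroni rule for families of comparisons.

The synthetic generator plants a known spatially varying coefficient
surface β(s) in a geo-clustered cohort, together with environmental
surfaces whose correlation with β(s) is controlled — so recovery,
calibration and power are all checkable.

## Worked example

```python
import numpy as np
import pgsmap as pm
from pgsmap.synthetic import LinearGradientBeta, EnvSurfaceSpec

cfg = pm.SimulationConfig(
    n_participants=5000, region=(0, 0, 20_000, 20_000),
    beta_surface=LinearGradientBeta(b0=0.0, bx=2e-5),   # 0 → 0.4 west→east
    env_surfaces=(EnvSurfaceSpec("sunshine_hours", "identity", 0.9),),
    use_genotypes=False, seed=42,
)
study = pm.simulate_cohort(cfg)
grid  = pm.build_hex_grid(cfg.polygon(), target_n=300)
fmap  = pm.map_associations(study.cohort, grid, pm.WeightKernel(),
                            pm.ModelSpec(trait="trait", pgs="pgs"))
print("beta range:", fmap.beta.min().round(3), "to", fmap.beta.max().round(3))
print("corr(fitted, true):",
      np.corrcoef(fmap.beta, study.truth.beta_at(grid.nodes))[0, 1].round(3))
W   = pm.contiguity_weights(grid)
env = pm.simulate_env_surfaces(grid, study.truth, cfg)
print(pm.compare_maps(fmap, env["sunshine_hours"], W, M=999, seed=1,
                      scheme="single"))
```

prints

```
beta range: 0.174 to 0.27
corr(fitted, true): 0.894
LeeTestResult(L=0.7961, M=999, p=0.002)
```

The fitted map recovers the planted gradient (correlation 0.89 with the
true surface) but with a compressed range — the shallow distance kernel
deliberately smooths node estimates toward the population mean (0.2). The
environmental surface generated at ρ = 0.9 with the truth is flagged as
strongly co-patterned with the *estimated* map: Lee's L = 0.80 at the
smallest p reportable with 999 permutations (2/1000).

## Command line

```bash
pgsmap all -c config.yaml     # simulate → score → map → compare
```

Subcommands `simulate`, `score`, `map` and `compare` run the stages
individually; every run writes a `manifest.json` with the seed and a
configuration hash. See `tests/test_cli.py` for a complete small config.

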