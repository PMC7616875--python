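# Methods

## Model

The pipeline estimates spatial variation in the association between a
polygenic score and a continuous trait. The generative model the package
assumes (and, in the synthetic module, simulates) is

    y_i = α + β(s_i) · G_i + γ_sex · sex_i + γ_age · age_i + ε_i,
    ε_i ~ N(0, σ²),

where `s_i` is participant i's planar residence coordinate (metres; all
geometry is Euclidean — no geodesy anywhere), `G_i` a standardized genetic
score, and `β(s)` a smooth coefficient surface. The estimand at an analysis
location `x` is `β(x)`, estimated by weighted least squares over the whole
cohort with inverse-distance weights

    w_i(x) = 1 / max(d(s_i, x), d_min)^p .

`p = 0.5` by default: a deliberately shallow kernel that trades
localisation for stability, smoothing node estimates toward the population
mean while leaving broad spatial patterns visible. The floor
`d_min = 50 m` (of the order of a residential postcode-area radius,
~118 m for a mean area of ≈44,000 m²) keeps weights finite for
participants living at a node; because WLS is invariant to rescaling all
weights, the distance unit itself does not affect estimates, only the
floor's relative position does. Standard errors are classical
precision-weight WLS errors — a convention choice, recorded in the map
metadata, since the inverse-distance weights are not literal precision
weights; no resampling-based uncertainty is attempted. Covariate values
are used as given (age is not re-centred per node). Participants with any
missing model column are dropped once, globally, before mapping
(complete-case), and nodes where the local normal equations are singular
are flagged `converged = False` rather than dropped.

## Analysis grid and spatial weights

Analysis locations form a regular hexagonal lattice: pointy-top offset
rows with horizontal pitch `s` and vertical pitch `s·√3/2`, anchored at
the region bounding-box lower-left and clipped to the study polygon
(nodes within half a spacing of the boundary are kept, so the lattice
covers the coastline/boundary). When a target node count is requested the
spacing is solved by bisection from the density relation
`n ≈ A/(s²·√3/2)` until the clipped count is within 5% of target. Any
consistent orientation of a regular hexagonal lattice is equally valid;
this one is fixed for determinism. Adjacency is first-order hex-edge
contiguity (distance ≤ 1.01·s), and the spatial weight matrix for map
comparisons is that contiguity, row-standardized, zero diagonal — the
canonical choice for a regular lattice.

## Lee's L and inference

For centred surfaces x̃, ỹ and weights V,

    L = n / Σ_i (Σ_j v_ij)² · Σ_i (V x̃)_i (V ỹ)_i / (‖x̃‖ ‖ỹ‖),

symmetric in its arguments, affine-equivariant, bounded by 1 in magnitude
under row-standardized weights, and reducing exactly to Pearson's r in the
self-only-neighbour limit. Moran's I is implemented alongside as the
univariate diagnostic.

Significance is by Monte-Carlo permutation. Two schemes are provided:

- **joint** (default): the (x, y) pairs are permuted together across
  locations, preserving the aspatial correlation and testing spatial
  arrangement of the pairing. This matches the behaviour of the standard
  spatial-statistics implementations of the test.
- **single**: only y is permuted. This is the exactly valid conditional
  test when one surface (e.g. an estimated coefficient map) is held fixed
  and the question is whether an exchangeable surface co-patterns with it.

The two-tailed p doubles the smaller one-sided tail, each estimated as
(1 + count)/(M + 1) with ties counted as exceedances, capped at 1; with
M permutations the attainable floor is 2/(M+1) — 1.9998×10⁻⁴ at
M = 10,000. A Bonferroni flag (`p < α/k`) supports families of
comparisons; with the conventional 15 environment-by-trait tests the
working threshold is ≈ 0.0033.

**Caveat on the joint scheme.** Any estimated coefficient map is smooth by
construction, so the joint scheme's exchangeability null is violated even
when the second surface is spatially random: the permutation distribution
is too tight and the test over-rejects (empirically, rejection rates of
0.6–0.75 at nominal 0.05 in this package's end-to-end simulations). This
is an inherent property of Monte-Carlo inference on Lee's L between a
smooth map and an independent surface, not an implementation artefact;
conclusions drawn from joint-scheme p-values should be read as evidence of
co-patterning relative to complete spatial randomness of both surfaces.
The end-to-end power and calibration checks in the test suite therefore
use the single scheme, whose validity is exact conditional on the map.

## Polygenic scores

Raw scores sum effect-weighted dosages over SNPs with discovery p strictly
below the threshold (matching the usual "p < t" convention); SNPs missing
from either side are dropped with a logged count, and an empty SNP set is
an error naming the threshold. Standardization uses the n−1 sample SD.
Threshold selection fits the full unweighted model
`trait ~ PGS + covariates` per threshold and takes the adjusted-R² argmax;
the incremental ΔR² over a covariates-only baseline is reported alongside,
and when no threshold's ΔR² clears the chance level for one added
regressor (≈10/n, the upper tail of χ²₁/n) the whole table is flagged
`null_signal`. Ties within 10⁻¹² break toward the more stringent
threshold (parsimony, determinism) with a warning. Dosages are assumed
pre-aligned to the GWAS effect allele; `reconcile_alleles` (flip swapped
alleles, resolve strand flips, drop ambiguous A/T and C/G SNPs) is
available for real data but unnecessary for the simulator's output. No LD
clumping is implemented — synthetic SNPs are independent — but a
pre-clumped SNP list can be passed to restrict scoring on real data.

## Synthetic studies

The generator emulates the structure of a geocoded birth cohort in a city
region; its defaults are the package's reference study conditions:

| parameter | default | rationale |
|---|---|---|
| n_participants | 5,000 | typical complete-case analysis size (4,000–8,000 band) |
| region | 40 × 30 km rectangle | city-region extent |
| n_clusters / cluster_sd | 8 / 2,500 m | settlement centres with suburban spread |
| n_snps / effect_fraction / effect_sd | 200 / 0.1 / 0.05 | sparse true signal; discovery z-scores straddle genome-wide significance |
| gwas_n | 50,000 | discovery-sample scale driving p-values |
| trait_noise_sd | 1.0 | PGS explains ~1% of variance at β ≈ 0.1, matching the low-R² regime of real scores |
| sex / age | Bernoulli(0.5); N(10.7, 0.12) | mid-childhood assessment |
| β surface | constant 0.1 (tests use gradients of 0–0.4 over 20 km) | weak average effect with detectable variation |
| attrition | off (γ = 0, rate 1.0) | opt-in PGS-linked logistic retention |

Locations are a Gaussian mixture over settlement centres, truncated to the
region by resampling offsets so mixture proportions are preserved exactly.
Genotypes are independent `Binomial(2, MAF)` dosages, MAF ~ U(0.05, 0.5);
the GWAS table reports the *true* effect, the effect-allele frequency and
a p-value from a simulated discovery z-statistic
`z = β·√(2·maf·(1−maf)·gwas_n) + N(0,1)`, so null SNPs have exactly zero
reported effect and uniform p. Traits are generated continuous; an
optional bounded-integer discretization (questionnaire-style 0–10 or 0–24
scales) exists but is off by default since the fitted model is linear
either way.

Environmental surfaces at grid nodes are transforms of the latent field
`ρ·z_β + √(1−ρ²)·z_noise`, where `z_β` is the standardized true β surface:
`identity` (smooth continuous, e.g. sunshine hours), `lognormal`
(positive, right-skewed, e.g. population density or deprivation indices —
log-transformed before comparison), `categorical3` (tercile levels, e.g.
village/town/urban). The independent noise component is **iid across
nodes** by default (`env_noise_smoothing = 0`): at ρ = 0 the surface then
satisfies the exchangeability null of the permutation test, which is what
makes the generator's null semantics match the inference machinery.
Setting `env_noise_smoothing > 0` produces more realistic autocorrelated
surfaces at the price of the caveat above. This is the main respect in
which passing tests understate the difficulty of real data: real
environmental surfaces are autocorrelated beyond their association with
any coefficient surface, and real cohorts add LD, ancestry structure and
informative missingness that the generator deliberately omits.

Every operation is deterministic given the configuration seed; independent
substreams (keyed by CRC32 of the operation name) decouple the stages, so
e.g. changing the number of SNPs does not perturb the simulated locations.

## Numerical choices

- Local fits solve batched 4×4 normal equations (`einsum` over nodes);
  with standardized regressors and ≤ ~20 coefficients this is accurate to
  well below the 10⁻⁸ tolerance the equivalence tests enforce against an
  independent solver and against statsmodels WLS.
- Rank deficiency is detected globally before mapping (error naming the
  collinear columns) and per node during mapping (flagged, not fatal).
- Permutations are generated as argsorts of uniform draws, vectorized
  across all M replicates; at M = 10,000 and ~1,000 nodes peak memory is a
  few hundred MB.
- Problem sizes in the test-suite simulations (300-node grids, 5,000
  participants, 50 replicates, M = 199–999) were chosen as the smallest
  sizes at which the statistical properties under test are stable.

## Known limitations

- No per-node confidence bands (the SE convention is nominal; bootstrap
  uncertainty for the whole map is out of scope).
- Linear, additive local models only; no non-linear or interaction terms.
- The simulator has no LD, no ancestry confounding (principal-component
  columns pass through as generic covariates), no measurement error in
  genotypes.
- Joint-scheme Monte-Carlo p-values between smooth maps are
  anticonservative (see above).
- Real-data PGS parity depends on upstream QC/clumping choices outside
  this package's scope.
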