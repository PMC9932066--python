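# Methods

This note documents the models, algorithms and numerical choices behind
`pollinet`, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what is computed, under which assumptions, and
where the genuinely open design decisions were settled.

## Networks and metrics

A site's network is the plant × visitor matrix of visit counts pooled over
all sampling rounds; rows and columns with zero totals are dropped at build
time (every metric here is undefined on empty margins) and labels are kept
lexicographically sorted so matrices are canonical. Genus-level networks
sum visitor columns sharing a genus; plant rows stay at species level. The
minimum-visit filter used before composition analysis removes visitor
species with fewer than 3 visits summed over all sites.

**Connectance** and **NODF** follow their standard definitions; NODF is
computed on the binarised matrix, pairs with equal fills contribute zero
(the strict-decrease rule), and the single-cell network is rejected as
undefined.

**H2′ and d′: integer margin-constrained extremes.** Both specialisation
indices standardise an information-theoretic quantity between the extremes
attainable under the observed margins. We compute these extremes over
*integer* tables, because observed tables are integer and because only the
integer extremes make the standardised index reach exactly 0 and 1 on the
analytic limit cases (margin-proportional tables, diagonal equal-margin
tables) at small m, where the continuous relaxation is visibly loose.

* `H2max`/`H2min`: exact by dynamic programming over rows (state: the
  remaining column totals; the entropy objective is additive over cells)
  whenever the table is small (≤ 5×6, m ≤ 28, with an enumeration budget as
  a backstop). Larger tables use heuristics: for the maximum, the floor of
  the independence table `r_i c_j/m` plus unit-wise allocation to the
  feasible cell furthest below its continuous target (order-invariant, and
  within the gap left by integrality in practice); for the minimum, greedy
  largest-block allocation `min(max remaining row, max remaining col)`.
  The standardised value is clamped to [0, 1].
* `d′min`: incremental greedy allocation of the visitor's total, one visit
  at a time to the plant with the smallest marginal divergence increase —
  provably optimal, since this is separable convex resource allocation.
* `d′max`: max-plus dynamic programme over plants with per-plant caps at
  the plant totals — exact. A visitor placing all visits on the single
  rarest plant attains the maximum whenever its total fits under that
  plant's cap.
* Both extreme computations depend only on the margins and are cached, so
  Δ-standardisation (hundreds of null tables with identical margins) pays
  the cost once.

**Modularity.** Barber's weighted bipartite modularity is maximised by
simulated annealing over joint row/column module assignments, in the style
of the QuanBiMo algorithm: single-node reassignment moves (including moves
into empty modules, which re-split clusters) plus occasional module merges,
Metropolis acceptance, geometric cooling (factor 0.99), and an initial
temperature calibrated so roughly half of the uphill probe moves would be
accepted. The chain keeps the best partition seen and stops after a
configurable number of temperature levels without improvement (default 40,
up to 400 levels, `2(R+C)` moves per level); the returned Q is recomputed
exactly from the definition on the best partition. All schedule knobs live
in `SAParams`; runs are reproducible given a seed. On networks small enough
to enumerate every partition, one seeded restart finds the global optimum
in ≥ 95% of runs (this is asserted in the test suite); observed networks
use 3 restarts by default.

## Null models and the Δ-transformation

Raw network metrics depend strongly on size and sampling intensity, so
each metric is reported as Δ = observed − mean over random integer tables
with exactly the observed margins, drawn from the independence-conditional
(multiple hypergeometric) distribution. Sampling is delegated to
`scipy.stats.random_table` (Patefield's sequential conditional algorithm);
single-row/column margins are handled directly since they admit exactly one
table. Defaults are 1000 draws per metric and 100 for modularity, whose
null replicates use a single annealing restart each (budget-matched to the
per-restart effort spent on the observed network). Draws on which a metric
is undefined would be rejected and resampled with a logged count; with
positive margins this defensive path is never exercised in practice.

Because the H2′/d′ extremes depend only on margins, the Δ for those metrics
is unaffected by any residual bias of the large-table extreme heuristics —
observed and null values share the same standardisation.

## 3D connectivity and scale of effect

Connectivity of patch i is `S_i = Σ_j exp(−α·d_eff_ij)·A_j` with
`d_eff = d_ij + λ·H_ij`, where `H_ij` sums the heights of buildings whose
distance to the straight centroid-to-centroid route is at most the corridor
radius (default 25 m). With λ = 0 this is exactly Hanski's
incidence-function connectivity. The functional form of the height
modification is a declared assumption: summed corridor height enters as
extra effective distance with weight λ (default 1 m per m of summed
height), the simplest monotone, units-consistent choice; λ and α are
configuration parameters and should be reported with any analysis. α
defaults to 0.002 m⁻¹ (mean dispersal distance 500 m, a typical wild-bee
scale). Routes are straight segments between centroids — no routing around
buildings, no edge-to-edge GIS distances.

Scale of effect selects, per response, the radius with the largest
*absolute* Pearson correlation (a signed maximum would never select strong
negative relationships such as bee richness vs impervious surface); ties go
to the smallest radius, the most local mechanism.

## Community composition and environmental fitting

The composition chain is the standard vegan-style sequence: minimum-visit
filter (≥ 3), square-root transform, Wisconsin double standardisation
(species maxima, then site totals), Bray–Curtis dissimilarity. Ordination
coordinates are supplied by principal-coordinate analysis (any 2-D
ordination of the dissimilarity matrix can be substituted; stress-minimised
NMDS is deliberately out of scope). Environmental vectors are fitted by
regressing the variable on the two ordination axes; significance uses
permutation of the variable over sites with the add-one estimator
`p = (1 + hits)/(1 + n_perm)` (never zero, unbiased under the null), with
99,999 permutations by default.

## Regression stage

Collinearity is screened by iteratively dropping the highest-VIF predictor
until all VIF ≤ 3. Count responses are fitted as Poisson GLMs and refitted
as negative binomial (maximum-likelihood dispersion) when the Pearson
χ²/df statistic exceeds 1.5 — the escalation rule is standard, the
threshold is a configurable package choice. Continuous responses use
ordinary linear models. Model selection fits every subset of at most 3
predictors and ranks by AIC (the NB AIC counts its dispersion parameter);
the family is fixed on the full candidate model so AICs are comparable
across subsets. Pseudo-R² for GLMs is 1 − deviance/null deviance. Patch
size is log-transformed (natural log) before modelling. Model residuals
are tested with Moran's I under row-normalised inverse-distance weights
(the weighting is configurable), using the randomisation-assumption
variance with kurtosis correction; significant autocorrelation sets a
`gls_recommended` flag — the generalised-least-squares refit itself is out
of scope. p-values are reported unadjusted throughout.

## Synthetic data generator

The generator emulates the study design the pipeline targets, and its
defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 11 | grassland patches on an urbanisation gradient |
| `impervious_range` | (5, 75) % | span of sealed-surface percentages |
| `cross_scale_corr` | 0.7 | pairwise correlation of impervious values across the 100/500/1000 m radii |
| `pool_sizes` | 105/38/22 bees/hoverflies/butterflies, 60 plants | regional species pools |
| `sampling_rounds` | 8 | transect walks pooled per site |
| `specialisation_strength` | 6 | trait-matching decay rate |
| `mean_visits_per_species` | 5 | expected visits per present species |
| `count_family` | negative binomial (size 1.5) | visit-count noise |

Impervious percentages at the three radii share a latent gradient
(`√ρ·gradient + √(1−ρ)·noise`, mapped linearly onto the range), giving an
exchangeable correlation structure calibrated to `cross_scale_corr`.
Group responses are log-linear with slopes per SD of the covariate: bee
richness −0.5 at 500 m, butterfly richness −0.6 at 100 m, hoverflies 0,
honey-bee visits +0.7 and flower abundance +0.4 increase with
urbanisation, and hoverfly/butterfly visitation increases with vegetation
height (+0.3). Directions mirror what urbanisation-gradient studies
report; the magnitudes are free generator parameters chosen to give
realistic signal at 11 sites, not estimates of any field dataset. Bare-soil
cover is generated collinear with impervious surface so the VIF screen has
a real collinear pair to resolve. Visits of each present visitor are
spread over plants with weight `abundance × exp(−s·|trait difference|)`
(one latent trait per species on [0, 1]); `s = 0` makes visitors
exchangeable, `s ≳ 3` produces the empirical Δ sign pattern
(Δ-connectance < 0, Δ-NODF < 0, Δ-modularity > 0), and the default 6
yields site-level H2′ around 0.2–0.4. Every present species contributes at
least one visit, so per-site richness follows its configured model exactly.

What the generator does *not* emulate: real urban morphology, within-season
phenology, weather-dependent detectability, observer effects, and spatial
autocorrelation of site covariates. Passing tests therefore demonstrate
correctness of the computations and internal consistency of the design,
not transferability of any particular effect estimate to field data.

## Pipeline reproducibility and problem sizes

`run_all` chains seven stages (landscape, visits, networks, Δ-metrics,
connectivity/scale selection, community, regression); the master seed
spawns fixed per-stage seeds, so identical configs reproduce identical
tables byte for byte and stages can be re-run in isolation. The manifest
records the config hash, stage seeds, timings and output registry.

The reported worked-example run (`scripts/acceptance.py`) uses 200 null
draws per metric and 60 for modularity across 11 sites × 2 resolutions —
enough that Monte-Carlo error on the Δ means is an order of magnitude
below their values — and 9,999 envfit permutations; both are package
choices for the bundled example and can be raised to the library defaults
(1000/100 and 99,999) via `run_all` arguments.

## Known limitations

* The large-table H2 extreme heuristics are approximations; their residual
  gap cancels in Δ-standardisation but absolute H2′ on large networks
  carries a small downward bias relative to the unknown exact integer
  extremes.
* Simulated annealing offers no optimality guarantee on large networks;
  restart counts and schedules are exposed for sensitivity checks.
* The Moran's I p-value is a normal approximation to the permutation
  distribution (exact variance, approximate shape) — adequate for the
  0.05 flag, not for extreme tail probabilities at n ≈ 10.
* GLS refits under detected spatial autocorrelation, true NMDS stress
  minimisation, and raster-based landscape processing are intentionally
  outside the package.
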