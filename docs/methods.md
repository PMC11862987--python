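# Methods

## Residence-time arithmetic and assay conversions

The canonical time unit throughout is hours, with 1 year = 365 days; all
unit views round-trip to 1e-9 relative. τ = V/Q requires Q > 0: a zero flow
rate raises a dedicated infinite-residence-time error rather than returning
infinity, because a sealed vessel is a qualitatively different system.

`max_generation_time` returns τ itself (the 1/μ convention), matching the
equivalence between a 1.9/h dilution rate and a ~30-minute generation time.
The stricter doubling-time convention ln 2/μ is available behind
`ln2_corrected=True` but is not the default; the two differ by a factor
ln 2 ≈ 0.69 and the 1/μ convention is the one consistent with the
chemostat steady-state condition μ = D.

Leucine-to-carbon conversion follows the standard chain: net CPM over the
kill control → DPM via counting efficiency (default 0.639) → moles of
leucine via specific activity (default 161 Ci/mmol, 2.22×10¹² dpm/Ci) →
protein via the leucine fraction of protein → carbon via the C:protein
ratio. The last two factors are not instrument properties and vary by
study; defaults are the standard literature values 0.073 g/g and
0.86 g C/g protein, exposed in `LeucineAssayConfig`. Net CPM below zero
clamps to 0 with a warning (tolerance configurable).

EcoPlate scoring blank-corrects, floors negative values at 0 (the dye is
irreversibly reduced), and calls a substrate positive when its mean blanked
OD strictly exceeds the 0.125 threshold. The community-level "mean
consumption" averages the *continuous* blanked OD over all
substrate × replicate wells; the binary calls are reported separately, since
both views are in common use and the thresholded count is coarser. The 31
canonical substrate names with their seven-category grouping ship as a data
file.

## The synthetic chemostat gradient

Each vessel integrates a Monod consumer-resource ODE over a 20-day horizon
(480 h), starting from fresh medium at the inflow concentration plus the
inoculum:

    dR/dt = (R_in − R)/τ − Σᵢ μᵢ(R) Nᵢ/yᵢ + η Σᵢ mᵢ Nᵢ/yᵢ
    dNᵢ/dt = (μᵢ(R) − mᵢ − 1/τ) Nᵢ + Iᵢ,   μᵢ(R) = μ_max,i R/(K_i + R)

with immigration Iᵢ = 0.01 · N_pool,i/τ — one percent of the abundance
diluted away per day, applied continuously and apportioned by fixed
inoculum-pool proportions. Continuous inflow avoids pulse artifacts; the
pool composition is fixed to the inoculum because a reintroduction source
kept at 4 °C does not track the vessels.

η is the fraction of maintenance losses remineralised to the resource pool
(default 0.7). This term is essential to the model's qualitative behaviour:
with negligible inflow at long τ the horizon is effectively a batch
incubation, and without remineralisation the biomass captured by the fast
initial bloom can never pass to slow-growing oligotrophs — total abundance
would crash with τ instead of plateauing, and no long-τ guild could come to
dominate. It also reconciles the ODE with the textbook single-species
equilibrium: at steady state the resource balance gives
N* = y D (R_in − R*)/(D + m(1 − η)), which reduces to the familiar
N* = y (R_in − R*) exactly when η = 1 (or m = 0).
`single_chemostat_equilibrium` exposes η with default 1 (the textbook
balance) and serves as the closed-form oracle for the integrator, which is
checked to 1% at τ ∈ {0.5, 5, 50, 500} h.

The default scenario is 49 chemostats log-spaced from 0.5 h to 3×10⁶ h
(≈ 340 years, seven orders of magnitude) and 60 taxa in four guilds.
Guild trait windows (drawn uniformly per taxon, seeded):

| guild      | n  | μ_max (1/h) | K_s        | m (1/h)       | role |
|------------|----|-------------|------------|---------------|------|
| short_tau  | 20 | 3.4–3.8     | 350–450    | 0.010–0.012   | survives D up to 2/h; blooms everywhere, decays at long τ |
| long_tau   | 20 | 0.045–0.055 | 0.8–1.2    | 1–2 ×10⁻⁴     | lowest R*; inherits the bloom's biomass at long τ |
| generalist | 10 | 0.70–0.78   | 18–22      | 0.006–0.008   | dominates mid-gradient residence times |
| noise      | 10 | 0.2–1.5 (log)| 100–500 (log)| 0.25–0.5 × μ_max | subordinate background, no gradient position |

The windows are deliberately narrow *within* guilds: with a single shared
resource, same-guild taxa otherwise competitively exclude one another inside
their own window and the losers' flat immigration-floor profiles would not
co-vary with their guild. Narrow windows make guild members rise and fall
together, which is the structure the clustering stage is meant to detect.
The short-τ maintenance window balances two pressures: large enough that
the guild's relative abundance declines with τ (its decayed-bloom residual
must stay below its mid-gradient immigration floor), small enough that the
residual stays detectable at depth 50,000 so the guild passes the > 70%
occupancy filter.

Noise taxa are "unstructured" in two senses: their maintenance is pinned to
25–50% of μ_max so they never hold a gradient position, and their expected
proportions receive a per-chemostat lognormal perturbation (σ = 1.5) before
multinomial sampling. They are minor background (~0.5% of reads) and fall
below the occupancy filter at long τ, so the filtered analysis set carries
the three structured guilds.

Counts are one multinomial draw per chemostat at read depth 50,000 from the
endpoint expected proportions; `GradientResult.resample(seed)` redraws
counts without re-integrating the ODEs. All stochasticity flows from one
scenario seed. The integrator is LSODA (rtol 1e-7) with a BDF retry at
tighter tolerance.

What the generator does *not* emulate: thousands of taxa, multiple
resources, dormancy, aggregation/biofilm, gradual trait continua. Passing
tests therefore demonstrate that the statistics recover planted structure
under idealised guild ecology, not that they would resolve the far noisier
structure of a real survey. One visible consequence: the three regimes are
so strongly partitioned that Bray–Curtis saturates between them and the
PCoA of the gradient is a horseshoe — axis 1 orders the regimes but its
rank correlation with log τ sits near 0.65 rather than higher values
expected for smooth turnover.

The companion phylogeny is a pure-birth tree (tips padded by a common 2%
holding time so all branch lengths are positive and the tree stays
ultrametric). Guild labels are assigned by evolving a Brownian liability
along the tree, adding unit tip noise, scaling the Brownian part by
`clustering_strength`, and slicing the liability order into blocks matching
the guild sizes: strength 0 is a random assignment, large strength confines
each guild to few clades.

## Niche overlap

Profiles are normalised per taxon (Σᵢ P_ij = 1), the resource-use
convention that makes the Pianka index the cosine similarity of gradient-use
distributions, bounded in [0, 1]. Per-site normalisation first is available
via `normalisation="site"`. The occupancy filter keeps taxa present in
*strictly* more than 70% of chemostats.

Null matrices (uniform, and zero-preserving uniform) are passed through the
same occupancy filter and normalisation as the observed matrix, so observed
and null pipelines are identical. p-values are add-one corrected,
(1 + #{null ≤ observed})/(n_rand + 1), one-tailed toward less overlap than
the null (the niche-partitioning direction); with 100 randomisations the
smallest attainable p is 1/101 ≈ 0.0099. The test's type-I error under its
own null is checked by simulation (uniform observed matrices, 50
replicates).

## Niche clustering

The distance is d = 1 − r² as printed in common practice; note it assigns
distance 0 to perfectly anticorrelated profiles. Whether the signed 1 − r is
intended is context-dependent, so both are exposed (`metric="1-r"`).
k-means runs on the rows of the distance matrix (each taxon featurised by
its distances to all taxa), mirroring the widespread practice of handing a
distance matrix directly to k-means; a PCoA-embedding alternative is behind
`embed=True`. 25 seeded restarts per k.

The elbow is the k maximising the second difference (discrete curvature) of
log WSS. The log scale makes the knee scale-invariant and responsive to
relative drops; on the raw scale the k=1→2 drop (the short-τ guild versus
everything else) dwarfs all later structure. When no knee stands out a
"weak elbow" warning accompanies the choice, and the full WSS curve is
always returned — the final k is ultimately a judgement call and the
machinery is built for a human override.

Niche profiles are combined relative abundances: per chemostat, the sum of
member taxa's count shares of the column total; the niche share is the mean
of that profile across chemostats. Trend fitting along log₁₀ τ delegates to
the statsmodels penalized B-spline GAM facility (penalty weight by
generalised cross-validation unless given), returning fitted values, 95%
intervals and deviance explained; this is deliberately thin plumbing.

## Phylogenetic dispersion

The change score d reconstructs internal values by recursive
daughter-averaging (tips carry 0/1) and sums |parent − child| over all
edges; trees must be rooted and strictly bifurcating. The scaled statistic
is D = (d_obs − mean d_Brownian)/(mean d_random − mean d_Brownian):
random shuffles of tip states (prevalence conserved) define D = 1, and
Brownian-threshold traits — a unit-rate Brownian character evolved along
the tree, the top-`prevalence` tips marked 1 — define D = 0. Rather than
assuming numeric agreement with any particular reference implementation,
the scaling is validated by its defining self-calibration property: over
replicate trees, mean D ≈ 0 for Brownian-threshold traits and ≈ 1 for
shuffles (bands ±0.15 at 200 replicates, 64 tips).

p_random = (1 + #{d_random ≤ d_obs})/(n_perm + 1), one-tailed toward
clustering; p_brownian analogous. The Cohen's-d effect size compares D with
D recomputed for each random shuffle, reusing the same two null-mean
denominators for every shuffle (cost O(n_perm), not O(n_perm²)); the sign
convention makes clustered traits positive. The implementation is
vectorised over permutations (one post-order pass per ensemble), so a
1000-permutation run on a 64-tip tree takes milliseconds.

## Diversity

Rarefaction is a single seeded multivariate-hypergeometric draw per column;
the analytic expectation E[S] = Σⱼ [1 − C(T−nⱼ, d)/C(T, d)] is used as the
test oracle rather than averaging many draws in the pipeline. Dissimilarity
defaults to Bray–Curtis on rarefied counts. PCoA is the classical Gower
double-centering followed by a symmetric eigendecomposition; negative
eigenvalues (non-Euclidean input) are reported with a warning, not
corrected, and axis signs are fixed deterministically (largest-magnitude
loading positive). Variance explained is relative to the sum of positive
eigenvalues.

## Pipeline

`run_all` derives each stage's seed as SHA-256(master seed, stage name) mod
2³¹, so stages are independently reproducible and adding a stage never
shifts another's stream. Identical configuration gives byte-identical
outputs (the manifest's wall-clock timestamps aside). A missing tree skips
the dispersion stage with a warning; any other failure aborts naming the
stage, keeping partial outputs. In the synthetic path the two *major*
niches (largest combined relative abundance) are the ones tested for
phylogenetic dispersion.

## Problem sizes

The shipped default scenario (49 ODE integrations of a 61-dimensional
system, depth 50,000) simulates in a few seconds; the full test suite runs
in well under a minute, with the heaviest pieces being the 50-replicate
type-I calibration of the overlap test and the 200-replicate D-statistic
self-calibration. These replicate counts were chosen so Monte-Carlo error
is comfortably inside the asserted bands.

## Known limitations

- Single shared resource: guild coexistence within a vessel relies on
  immigration and non-equilibrium dynamics, not stable coexistence theory.
- The 1 − r² distance conflates correlated and anticorrelated taxa by
  design; use `metric="1-r"` when that matters.
- The elbow heuristic, like all of them, can be indecisive on smooth WSS
  curves; the weak-elbow warning flags this but the scan range caps k.
- D is undefined on degenerate trees where the two null means coincide
  (raised as an error), and its variance grows at prevalence extremes.
- EcoPlate parsing expects the bundled 31-substrate layout; raw plate-reader
  exports are out of scope.
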