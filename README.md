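# taunich

Niche analysis along residence-time gradients in chemostat microbial
communities.

## The problem

Residence time (τ) — the mean time a passively transported cell or molecule
spends in a well-mixed flowing system, τ = V/Q — is a master variable of
microbial ecology in flowing habitats. Its reciprocal, the dilution rate
D = 1/τ, sets the slowest growth rate a planktonic population can sustain
without washing out, so a gradient of residence times spanning minutes to
centuries moves a community from washout-dominated to resource-limited
regimes. `taunich` provides the statistical machinery to ask whether taxa
*partition* such a gradient into niches:

- **Residence-time arithmetic** — τ = V/Q, D = 1/τ, the maximum generation
  time at a given τ, and assay conversions (flow-cytometry absolute counts,
  ³H-leucine incorporation to μmol C/h, Biolog EcoPlate carbon-use scoring).
- **Gradient-use overlap** — each taxon's profile P<sub>ij</sub> (relative
  abundance of taxon *j* at residence time *i*, normalised per taxon) is
  compared pairwise with the Pianka index
  O₁₂ = Σᵢ P<sub>i1</sub>P<sub>i2</sub> / √(Σᵢ P²<sub>i1</sub> · Σᵢ P²<sub>i2</sub>),
  and the observed mean overlap of taxa occupying > 70% of chemostats is
  tested against two ensembles of 100 randomised chemostat × taxa matrices
  (all-uniform, and zero-preserving uniform), one-tailed toward *less*
  overlap than chance.
- **Niche identification** — k-means on the correlation distance
  d = 1 − r² between gradient profiles, with the niche count chosen at the
  elbow of the within-cluster sum of squares, and combined per-niche
  relative-abundance profiles along τ.
- **Phylogenetic dispersion** — the Fritz–Purvis D statistic of binary niche
  membership, scaled between a Brownian-threshold expectation (D = 0,
  clustering) and a random-shuffle expectation (D = 1), with permutation
  p-values and a Cohen's-d effect size.
- **Diversity** — rarefaction (multivariate hypergeometric), richness,
  inverse-Simpson evenness E = D⁻¹/S, Bray–Curtis dissimilarity and
  classical PCoA.
- **A synthetic community generator** — a Monod consumer-resource chemostat
  ODE integrated per vessel over a 49-point τ grid spanning seven orders of
  magnitude (0.5 h to 3×10⁶ h), with planted short-τ / long-τ / generalist
  guilds, unstructured noise taxa, continuous immigration worth 1% of daily
  turnover, multinomial read sampling, and a phylogeny on which guild
  membership is clustered. Every downstream stage is validated against this
  known ground truth.

The analysis stages are sklearn-style estimators (`NicheOverlapTest`,
`NicheKMeans`, `PhyloDTest`, `PCoA`) with plain-function wrappers, plus a
`taunich` command-line interface.

## Worked example

The fastest vessel of a gradient reaching dilution rate 1.9/h:

```sh
$ taunich rates --volume 40 --flow-rate 76
residence time:      0.526316 h = 31.5789 min = 0.0219298 d = 6.00817e-05 y
dilution rate:       1.9 /h = 45.6 /d = 16644 /y
max generation time: 0.526316 h = 31.5789 min = 0.0219298 d = 6.00817e-05 y
```

A population needs a generation time of roughly half an hour to persist
there. Running the niche analysis on the bundled synthetic gradient:

```python
from taunich.simulate import default_scenario, simulate_gradient
from taunich.overlap import NicheOverlapTest
from taunich.clusters import NicheKMeans

result = simulate_gradient(default_scenario(seed=0))
test = NicheOverlapTest(n_rand=100, seed=0).fit(result.community)
print(f"taxa in >70% of chemostats: {test.n_taxa_used_}")
print(f"observed mean Pianka overlap: {test.observed_mean_:.3f}")
for model, s in test.result_.null_summary.items():
    print(f"  {model:16s} null mean {s['mean']:.3f}  p = {s['p']:.4f}")

niches = NicheKMeans(k="auto", random_state=0).fit(result.community)
print(f"elbow-selected k: {niches.k_}")
```

prints

```
taxa in >70% of chemostats: 50
observed mean Pianka overlap: 0.445
  uniform          null mean 0.751  p = 0.0099
  zero_preserving  null mean 0.751  p = 0.0099
elbow-selected k: 3
```

The 50 widespread taxa overlap far less along the gradient than either null
ensemble allows (p ≈ 0.01): the gradient is partitioned. The elbow of the
within-cluster sum of squares finds the three planted structured guilds
(short-τ, generalist, long-τ); the ten noise taxa fall below the occupancy
filter. The full pipeline — simulation, diversity, ordination, overlap,
clustering, phylogenetic dispersion, with one master seed and a manifest —
runs as `taunich all --seed 0 --out results_dir`.

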