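# nectarevo

Eco-evolutionary analysis of floral nectar sugar composition: how much of
the variation in the **proportion of sucrose in nectar** across
insect-pollinated plant species is explained by phylogeny, by floral
morphology, and by their overlap — and how that phylogenetic signal relates
to paleoclimate and to the specialisation of present-day plant–pollinator
networks.

The package is aimed at evolutionary ecologists who want the full analysis
chain as tested, reusable Python: phylogenetic eigenvector regression (PVR)
with binomial errors, likelihood-ratio variance partitioning, clade-age and
paleotemperature mixed models, and bipartite-network specialisation (d′),
plus a synthetic-data generator that emulates the statistical structure of
such a study so every stage can be exercised without external data.

## The statistics at the core

**Response.** Nectar sugar composition is summarised per species as the
molar proportion of sucrose among the three nectar sugars,
p = [sucrose] / ([sucrose] + [glucose] + [fructose]) ∈ [0, 1]. A secondary
response is the fructose share within hexoses. Proportions are modelled
with a fractional-binomial likelihood (Bernoulli form with fractional
successes, unit weights) under a logit link,
ℓ = Σᵢ yᵢ log μᵢ + (1 − yᵢ) log(1 − μᵢ),
fitted by IRLS; mixed models add nested random intercepts whose marginal
likelihood is evaluated by a Laplace approximation.

**PVR.** The patristic distance matrix D of a dated phylogeny is
double-centred, B = −½ J D∘D J with J = I − n⁻¹𝟙𝟙ᵀ (the PCoA Gower
transform); the eigenvectors of B with positive eigenvalues are candidate
predictors carrying phylogenetic structure. Relevant axes are chosen by
stepwise AIC under the fractional-binomial GLM, or by iteratively removing
residual phylogenetic autocorrelation (Moran's I with inverse-distance
weights and a permutation test).

**Variance partition.** With pseudo-R² = 1 − exp(−(2/n)(ℓ_M − ℓ₀)) from
fits of the trait block (T), the eigenvector block (P), and both (F):
pure traits a = R²_F − R²_P, pure phylogeny c = R²_F − R²_T, and
phylogenetically structured traits b = R²_T + R²_P − R²_F, so that
a + b + c = R²_F identically.

**Clade age and paleoclimate.** Family and order crown ages are the depths
of each clade's most recent common ancestor. A global mean surface
temperature series on a 0.2-My grid (100 Ma → present) is interpolated
linearly at each family's crown age; sucrose proportion is regressed on
family age (GLM, and GLMM with a random order intercept) and on the origin
temperature (GLMM with family-in-order random intercepts).

**Network specialisation.** Site-by-round visitation networks are divided
by their own totals, averaged cell-wise, and rescaled to the grand total
(the meta-network). For each species, d is the Kullback–Leibler divergence
of its partner-use distribution from partner availability, and
d′ = (d − d_min)/(d_max − d_min) ∈ [0, 1]; for integer matrices the bounds
are exact over integer allocations (the minimum via a provably exact greedy
rule for separable convex objectives, the maximum at the scarcest partner).
Gaussian (mixed) models then relate pollinator d′ to the visit-weighted
sucrose proportion of the plants each pollinator visits.

## Worked example

The whole pipeline on a synthetic study (200 species, ~40 families, 8 sites
× 3 rounds of network sampling):

```bash
$ nectarevo all --seed 7 --out demo
synthetic dataset written to demo
pure phylogeny 0.034, pure traits 0.021, shared -0.001, total 0.054
family-age slope 0.0220 (AIC 214.36)
paleotemperature slope 0.0936 (AIC 217.82)
sucrose-d' slope 0.034 (95% CI -0.125..0.194)
pipeline complete
```

Reading the output:

* the variance partition attributes 3.4% of the (pseudo-R²) variation in
  sucrose proportion to phylogeny alone, 2.1% to floral traits alone, with
  a negligible shared fraction — the fractions always sum to the full
  model's R² exactly;
* the sucrose proportion increases with family crown age
  (+0.022 logit units per My on this draw) and with the temperature at the
  family's origin (+0.094 logit units per °C; the generator injected 0.1);
* the sucrose–d′ slope from the meta-network model is positive but its 95%
  confidence interval spans zero on this single draw — the simulation
  experiments below quantify the detection rate.

Each stage also writes machine-readable artifacts (`partition_report.json`,
`d_prime_pollinators.csv`, …) under the output directory; subcommands
(`simulate`, `pvr`, `partition`, `clade-models`, `paleo-models`, `network`)
run stages individually on the same directory layout.

## Input formats

* **Tree** — Newick with branch lengths in My; clade map CSV
  `species,family,order`.
* **Traits** — CSV indexed by `species`: `sucrose_proportion`,
  `fructose_within_hexoses`, `tube_length_mm`, `symmetry`
  (actinomorphic/zygomorphic), `colour`, `flower_type`, `pollination_type`.
* **Temperature** — CSV `time_ma,gmst_c` on a uniform, descending grid.
* **Networks** — edge-list CSV `site,round,plant,pollinator,guild,count`
  with guilds `solitary_bee | bumble_bee | hoverfly | honey_bee`.

See `docs/methods.md` for the model assumptions, the synthetic generator's
design and its limits, and the numerical choices.
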