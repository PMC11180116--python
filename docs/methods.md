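# Methods

This note documents the models implemented in `nectarevo`, the design of
the synthetic study generator, and the numerical choices, in enough detail
to judge what the package's tests do and do not demonstrate.

## Response variables and likelihood

Both responses are continuous species-level proportions: the molar sucrose
share of nectar, p ∈ [0, 1], and the fructose share within hexoses.
They are modelled with a **fractional-binomial likelihood** — the Bernoulli
log-likelihood evaluated at fractional successes with unit weights,

    l = sum_i [ y_i log mu_i + (1 - y_i) log(1 - mu_i) ],   logit(mu) = X beta.

Exact zeros and ones in the response are retained (the likelihood is finite
for interior mu); fitted values are clipped to [1e-10, 1 − 1e-10] inside
IRLS only. IRLS iterates to max |Δβ| < 1e-8 or 100 iterations; the
coefficients agree with `statsmodels` GLM(Binomial) to 1e-6 (cross-checked
in the test suite).

This is a *quasi*-likelihood: it implies observation-level dispersion of
binomial magnitude, mu(1 − mu), regardless of the true dispersion of the
proportions. Two consequences matter for interpreting the simulation
experiments:

1. **Information ceiling.** The Fisher information about any coefficient is
   bounded by Sum_i mu_i(1 − mu_i) ≤ n/4, however precise the proportions
   are. Effects must be large relative to this scale to be detected.
2. **Variance-component attenuation.** With few species per family, the
   family-level random-intercept variance is weakly identified and its ML
   estimate often collapses to zero (under-dispersed responses make this
   collapse more, not less, likely). The Laplace-approximate marginal
   likelihood itself is accurate — it matches 80-node Gauss–Hermite
   quadrature to ~0.1 over the plausible variance range — so this is a
   property of the estimand, not of the approximation.

Mixed models use random intercepts with nested grouping (family within
order), a Laplace approximation around the penalised mode (inner Newton to
1e-10), and L-BFGS-B over fixed effects and log-standard-deviations
(bounds [−7, 3], deterministic start from the GLM fit). AIC counts one
parameter per fixed effect plus one per variance component; AICc adds the
small-sample correction and is used for the network models, where n/k is
small.

## PVR and the variance partition

Eigenvectors come from the Gower double-centring B = −½ J (D∘D) J of the
patristic distance matrix; axes with eigenvalue > 1e-10 × the largest are
retained, unit-normalised (not rescaled by √eigenvalue — regressions are
invariant to column scaling, and unit norm keeps the conditioning of the
design matrix independent of the eigenvalue spectrum), and sign-fixed so
each column's first nonzero entry is positive, making output reproducible
across LAPACK implementations.

Selection is two-stage, mirroring the flow of the field's PVR analyses:
stage 1 selects eigenvectors against the response alone (stepwise AIC,
direction "both", starting from the intercept, ties broken by candidate
index; or the Moran's-I alternative: greedily add the axis that most
shrinks the absolute residual autocorrelation until its permutation p-value
reaches 0.05 — the stopping rule is our choice, documented here because no
standard one exists). Stage 2 runs exhaustive all-subsets inference over
the surviving eigenvectors plus floral traits and keeps the union of
predictors of the ΔAIC < 2 model set. Note that this union *by
construction* tends to include one-parameter supersets of the best model
(any predictor whose χ² improvement is positive lands within 2 AIC), so it
is a deliberately inclusive screen; the partition is computed from it.

The three fractions are a = R²_F − R²_P, b = R²_T + R²_P − R²_F,
c = R²_F − R²_T from the likelihood-ratio pseudo-R²
(1 − exp(−(2/n)(l_M − l_0))); additivity a + b + c = R²_F is an algebraic
identity and is asserted to 1e-10. Both the unadjusted and the adjusted
variant (Nagelkerke rescaling by R²_max followed by the (n−1)/(n−k−1)
small-sample correction, floored at zero) are always reported; negative
shared fractions are possible, reported as-is, and flagged with a warning.
When stage 1 retains nothing (typical for the fructose response), a
configuration flag lets all eigenvectors enter stage 2.

## Clade ages and paleotemperature

Crown age = depth of the clade's MRCA; on non-ultrametric trees node depth
is the mean distance to descendant tips (with a warning); monotypic clades
fall back to the stem age, flagged. Temperature at origin is linear
interpolation of the 0.2-My-grid GMST series at the family crown age; ages
beyond the grid raise rather than extrapolate.

Three models probe the evolutionary depth of the signal: family-age GLM,
family-age GLMM (order random intercept), and the paleotemperature GLMM
(family-in-order random intercepts, optional floral covariates). The
acceptance script measures both the slope recovery and how often the
temperature model beats the age model by AIC under the generator's
temperature mechanism. At the package's default scale the slope is
recovered well (mean within a few percent of truth) but the AIC comparison
almost never favours the temperature model: its extra variance component
costs 2 AIC while the age-orthogonal share of the temperature covariate —
the only part the age model cannot mimic — contributes well under one unit
of log-likelihood given the information ceiling above (≈ 0.5 β² ·
var_orth(T) · Σ mu(1−mu), with β = 0.1/°C and a few °C² of orthogonal
variance inside the ≤ 40-Ma crown-age window of a 200-tip tree). Detecting
it would need either several-fold more information (many more species, or
genuinely binomial observation noise) or family ages spanning the strongly
non-linear deep part of the climate curve. The test encoding this
comparison is left failing rather than weakened; it documents a real
power limit of the desk-scale emulation, not a defect of the models.

## Meta-network and d′

Local networks are standardised by their own totals, averaged cell-wise
over *all* networks (structural zeros included; a present-only mean is
available by option), and rescaled by the grand total times a correction
factor (default 1, a no-op, so the total is conserved exactly; a different
multiplier can be supplied when a workflow calls for one).

d is the KL divergence of a species' partner-use distribution from partner
availability (opposite-margin shares of the same, possibly
guild-restricted, meta-network, including the focal species' interactions;
partners with zero availability are excluded — they are not resources).
For continuous matrices d_min = 0 and d_max = ln(1/q_min). For integer
matrices the bounds are computed over integer allocations: d·A is
separable-convex in the allocation, so greedy marginal-increment descent is
provably exact for the minimum, and the maximum is attained at a vertex
(all units on the scarcest partner); both are validated against exhaustive
enumeration in the tests.

The d′ models are gaussian ML fits (statsmodels OLS / MixedLM) of d′ on
visit-weighted sucrose exposure, tube-length exposure, and zygomorphy
share, with taxonomic random intercepts per the guild rules (none for
bumble bees, genus for hoverflies, family otherwise; a level with fewer
than three groups is dropped with a warning). Model choice is all-subsets
AICc with a Δ < 2 best set; the reported sucrose slope and CI come from the
full model, so inference exists even when selection drops the term. When
the group variance sits on the boundary (the common case for taxonomically
unstructured data) the fit is exactly OLS and the reported covariance is
HC3 heteroskedasticity-robust: specialists' d′ values are intrinsically
noisier than generalists', and the homoskedastic Wald interval is
anticonservative there.

## The synthetic study generator

All four inputs are generated deterministically from one seed (independent
substreams per stage, so changing e.g. the network settings does not
perturb the tree).

* **Tree** — forward Yule simulation to exactly n tips, rescaled to height
  100 My. Families/orders are the clades rooted where lineages cross fixed
  depths (25 / 50 My by default, giving roughly 40 families and 12 orders
  at 200 species); nesting is guaranteed by construction. This yields
  family crown ages only up to the cut depth — much shallower than real
  angiosperm families — which is the main reason the temperature-vs-age
  contrast is weak at desk scale (above).
* **Temperature** — a monotone piecewise-linear greenhouse-to-icehouse
  profile from 33 °C (100 Ma) to 13 °C (present) with a sharp ~5 °C step
  at the Eocene–Oligocene transition (~34 Ma), plus stationary AR(1)
  wiggles (marginal sd 1.5 °C, lag-1 correlation 0.9 on the 0.2-My grid).
  A featureless smooth trend would make temperature-at-origin almost
  collinear with clade age; the step is the best-documented feature of the
  real curve and is what gives the temperature-vs-age comparison content.
* **Sucrose trait** — logit(p) = −0.5 + 0.1·(T(family crown age) − 23 °C)
  + BM(σ = 0.1 per √My), i.e. a tip sd of ~1 logit unit of phylogenetic
  noise; the latent phylogenetic share, 1/(1 + π²/3) ≈ 0.23, is in the
  range a strongly conserved floral trait would show. Corolla tube length,
  symmetry, and the fructose share are linked latent-BM derivatives; colour
  and flower type are uniform categoricals (deliberately uninformative).
* **Networks** — 8 sites × 3 rounds × 100 multinomial visits (the per-
  network effort of the study system), 123 network plants and 120
  pollinators (one honey bee; others split ~150:13:24 solitary
  bee:bumble bee:hoverfly). Each pollinator has latent specialisation
  s ~ Beta(2,2); its Dirichlet preference concentration decays
  geometrically in s (specialists concentrate on ~one plant), and its
  affinity for sucrose-rich plants is tilted by exp(2γ(s − ½)z): with
  γ > 0, sucrose-rich (deep, exclusive) flowers are avoided by generalists
  — hence rare — and favoured by specialists, producing the positive
  d′–sucrose association; γ = 0 removes every sucrose-linked structure and
  is the calibrated null.

What the generator does **not** emulate: intraspecific variation in nectar
chemistry, unequal sampling effort across sites, taxonomy correlated with
ecology (pollinator genera/families are random labels, so the taxonomic
random effects are true nulls), plant phenology across rounds, and real
taxonomic imbalance (old monotypic families). Passing tests therefore show
that the estimators recover the *injected* structure at realistic sizes and
noise, not that the original field results are reproduced — the study's raw
data are not published in a form that would allow that.

## Numerical conventions

* 0·ln 0 = 0 throughout the KL computations.
* Moran's I uses inverse patristic distance weights with zero diagonal
  (1 − D/D_max available by option); permutation p-values use a stated seed
  and count, upper tail by default (phylogenetic signal is positive
  autocorrelation).
* Eigenvector sign convention and all stepwise/subset tie-breaks are
  deterministic, so identical configurations are byte-reproducible.
* AICs are only compared between fits tagged with the same response hash;
  comparing across responses raises.
* Degenerate inputs raise typed errors naming the offending labels
  (aliased design columns, unmatched species, ages beyond the temperature
  grid, zero-variance traits, empty networks).

## Scale choices

Default simulation sizes (200 species, 100-tip trees for the paired signal
experiment, 25–50 replicates per experiment) were chosen so the full test
suite and the acceptance script each finish in a few minutes on one CPU
while keeping every detection rate they assert comfortably away from its
threshold; a study-scale configuration (414 species, 16 sites, 188
pollinators) ships as `study_scale_config` for users who want the full-size
emulation.
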