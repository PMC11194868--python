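# Methods

This note documents the statistical machinery, the synthetic-data
generator's assumptions, the numerical choices, and what the validation
studies do and do not establish.

## Data model and derived variables

The unit of analysis is a small census area with a child population
`E_i` (ages 0–14), an asthma count `Y_i`, prevalence `100·Y_i/E_i`, an
area deprivation score (SEIFA-IRSD style: lower = more disadvantaged)
with its national decile, and the percentage of Indigenous residents.
Analysis retains areas with at least 5 children, total population at
least 200, a recorded deprivation score, and at least one retained
neighbour.  The isolation rule runs after the population filters and
iterates to a fixed point, because dropping an area can isolate its
last neighbour; the order of the non-spatial filters does not affect
the result, only the attributed reason.

Derived covariates follow the conventions of the census analysis this
package mirrors: deprivation deciles collapse pairwise into five
categories (deciles 1–2 most disadvantaged … 9–10 most advantaged), and
the Indigenous percentage is dichotomised at its median across retained
areas, the upper group inclusive of the threshold.  The median is
recomputed from the data at hand rather than hard-coded: the published
2.08% cut-off is itself a data median, so it reproduces automatically
only on data resembling the census table.

## Spatial weights

Queen contiguity: areas are neighbours if their polygon boundaries come
within 10⁻⁸ coordinate units of one another at any point (vertex or
edge; the tolerance absorbs serialisation round-off).  Moran statistics
use the row-standardised matrix (`w_ij = 1/deg(i)`), the CAR precision
uses the binary matrix — the GeoDa/CARBayes pairing; with
row-standardised weights the mean of the local Moran statistics equals
the global statistic exactly, which the suite tests.

## Moran's I and LISA

Pseudo p-values use the permutation convention `(r+1)/(M+1)` and are
one-sided in the direction of the observed departure from expectation
(−1/(n−1) globally; −z_i²/(n−1) for the conditional local test).  A
consequence worth stating: the two directions together make the
procedure behave like a two-sided test at level 2α, so on null data the
rate of significant *positive* calls — the hot-spot direction the
analysis cares about — is what sits at the nominal α.  The calibration
study measures exactly that rate.  Local p-values hold area i's value
fixed and permute the remaining n−1 values across its neighbours; one
bank of permutations is shared across areas for speed (draws stay
exchangeable).  For n ≤ 8 both tests can enumerate all permutations,
which the suite compares against brute-force oracles.

Classification defaults are GeoDa-style: α = 0.05, 999 conditional
permutations, no multiple-testing correction (a Benjamini–Hochberg
mode exists but is off by default, matching how LISA maps are usually
read).  Ties: a value exactly at the mean (z_i = 0) takes its quadrant
from the sign of the spatial lag alone.

## CAR models

Both models are Poisson log-linear with offset `log E_i` and the
indicator design (four deprivation categories against most advantaged;
high-Indigenous against low; optional interaction expansion).

**Leroux.** `φ` has precision `τ⁻²[ρ(D−W) + (1−ρ)I]`.  Updates: β as a
block random-walk Metropolis step preconditioned with the
Poisson-GLM (IRLS) covariance; φ by Metropolis within Gibbs swept one
graph-colour class at a time (greedy colouring; no two simultaneously
updated areas are adjacent, so the sweep is a valid conditional
update); τ² by its conjugate Inverse-Gamma draw; ρ by random-walk
Metropolis on (0, 1) with the prior normalising constant computed from
the precomputed eigenvalues of D−W.  φ is recentred to mean zero each
sweep with the mean absorbed into the intercept (identifiability).
With the likelihood switched off the φ update becomes an exact Gaussian
Gibbs draw, which is how the prior-recovery and joint-moment checks are
run.

**Localised.** `Y_i ~ Poisson(E_i exp(x_i'β + λ_{Z_i} + θ_i))` with
ordered intercepts λ₁ < … < λ_G, iid `θ_i ~ N(0, σ²)`, and label prior
`f(Z_i = g | δ) ∝ exp(−δ(g − G*)²)`, `G* = (G+1)/2`, δ ~ Uniform(1, 10)
— the penalty formulation standard in the localised-cluster disease-
mapping literature.  The design drops its intercept (the λ play that
role).  Z is a vectorised discrete Gibbs draw (the penalty does not
couple areas); λ proposals violating the ordering are rejected; δ uses
Metropolis with the label-prior normalising constant included; θ is a
vectorised element-wise Metropolis step; σ² is conjugate.  An empty
class is legal — G is a maximum.

Initialisation matters for this model and is deliberately staged:
labels and intercepts start from a 1-D k-means of the
covariate-adjusted log-SMR (classes may be unequal in size, so
clustering beats equal-count binning), δ starts at its lower bound so
the likelihood rather than the penalty seeds the allocation, and θ is
held at zero for the first half of burn-in.  Without the last step the
chain reliably falls into a trap where θ absorbs block-level misfit
before the labels settle, after which no single-coordinate update can
exchange a θ offset for a label change.  λ gets a N(0, 10) prior rather
than the diffuse N(0, 10⁵) used for β: an emptied class's intercept
does a prior random walk, and a diffuse prior would let it drift
permanently out of reach of the data.

**Priors and defaults.** Coefficients N(0, 10⁵); random-effect
variances Inverse-Gamma(1, 0.01); ρ Uniform(0, 1) (estimated, with an
option to fix it); δ Uniform(1, 10).  Proposal scales self-tune during
burn-in towards ~45% acceptance for scalar moves and ~25% for the β
block.  The default run length is 30,000 iterations with 10,000
burn-in and thinning 10 (the package's desk-scale setting; national
census analyses use 300,000/100,000, available through the same
configuration).  Fixed seed gives bitwise-identical chains.

**WAIC and Geweke.** WAIC uses the retained pointwise log-likelihood
matrix: `lppd` by log-sum-exp (stable for log-likelihoods below −700),
`p_waic` as the sum of pointwise sample variances (ddof 1).  The Geweke
z compares the mean of the first 10% of a chain with the last 50%,
with batch-means standard errors; a constant chain warns and returns
NaN rather than failing silently.

## Synthetic-data generator

The generator's defaults are the study conditions of the census table
it emulates, fixed once from the published descriptives: child
populations lognormal with mean 1,991 and SD 1,228, clipped to
[10, 7,889]; total population from a Beta-distributed child share
(mean 0.183); the deprivation score is neighbourhood-averaged Gaussian
noise rescaled to mean 999 / SD 82.5, with one smoothing pass so its
Moran's I sits near 0.6; the Indigenous percentage is lognormal
(median 2.08) built from noise smoothed three times so its Moran's I
sits near 0.75.  Deciles are rank-derived with group sizes differing by
at most one.  Counts are Poisson with covariate effects at the
published prevalence-ratio scale (0.99, 1.01, 1.04, 1.10 across the
deprivation gradient; 1.13 for high Indigenous density) and a Leroux
field with ρ = 0.99, τ² = 0.3; the intercept is calibrated so the
area-mean expected prevalence is 6.27%, giving a prevalence SD near the
published 1.95.  On a 30×30 queen lattice the resulting prevalence
Moran's I is ≈ 0.45: Poisson noise and lattice geometry cap the
achievable autocorrelation below the ≈ 0.6 seen in the national data,
so that value should be read as a regime (strong positive
autocorrelation, minimum pseudo-p) rather than a number the lattice
reproduces.  Leroux fields are sampled exactly (Cholesky of the
precision, solve against standard normals), not by MCMC.

What the generator does not emulate: irregular area geometry and the
long-tailed degree distribution of real contiguity graphs, within-area
age/sex structure, missingness patterns, and any real spatial
confounding between deprivation and Indigenous density beyond what the
smoothing induces.  Tests passing on this generator show the
estimators are correct under the model's assumptions at census-like
marginals; they do not show the model assumptions fit any particular
real dataset.

## Validation studies

* **Permutation exactness** — for n ≤ 8, exhaustive global and local
  pseudo p-values equal brute-force enumeration oracles exactly.
* **Type-I calibration** — 500 iid fields on a 6×6 lattice; the rate of
  significant positive-autocorrelation calls at α = 0.05 falls within
  two binomial SEs of 0.05.
* **Sampler correctness** — prior-only runs recover the
  Inverse-Gamma(1, 0.01), Uniform(0, 1) and Uniform(1, 10) marginals
  (KS at the 1% level); fixed-(ρ, τ²) Gibbs on a 3-node path reproduces
  the exact N(0, Q⁻¹) covariance; β posteriors match a Poisson-GLM
  oracle when φ = 0 and an independently coded iid-random-effect
  sampler when ρ = 0.
* **Coverage** — 20 replicates of a 20×20 lattice with generating
  PRs (1.04, 1.10, 1.13); each coefficient's 95% CrI covers its truth
  in ≥ 17/20 replicates.  Observed coverage runs a few points below
  nominal (~88–92%); part of this is spatial confounding — the
  deprivation and Indigenous covariates are themselves spatially
  smooth, so the CAR field absorbs some of their signal, a known
  property of these models (coverage improves when the same experiment
  is rerun with spatially unstructured covariates) — and the remainder
  is desk-scale Monte-Carlo error.
* **Model selection** — the localised G = 5 model beats Leroux by WAIC
  on data simulated from the localised process itself (labels iid from
  the penalty prior).  This nested fixture is a deliberate choice:
  with *contiguous* cluster blocks at census-scale counts, a smooth
  Leroux field fits the steps well and its likelihood gain from
  tracking Poisson noise outweighs the penalty difference, so WAIC
  prefers it — an instance of WAIC favouring the more flexible
  misspecified model, not a defect of either sampler.  The contiguous
  generator remains in the package and is used for the partition-
  recovery check (two well-separated blocks, ≥ 90% of areas grouped
  correctly).

## Known limitations

* Single-chain inference; between-chain diagnostics (R-hat) are out of
  scope, convergence is monitored per-parameter with Geweke z.
* The localised model's posterior is multimodal by construction;
  the staged initialisation finds the intended mode on separable data
  but no guarantee exists for arbitrary inputs.
* Planar coordinates are assumed for queen contiguity; great-circle
  geometry and distance-band weights are not implemented.
* The exclusion rules treat the child-population column as the count
  the "< 5 children" rule refers to.
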