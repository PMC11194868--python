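# spatialprev

Small-area spatial analysis of disease prevalence, built around the
workflow used for childhood asthma in the 2021 Australian census:
exploratory spatial autocorrelation and hot-spot detection at the
census-area (SA2) level, followed by Bayesian spatial regression of
area counts on sociodemographic covariates.  It is a library first —
the `examples/` scripts show each capability — with a thin
`spatialprev` command for end-to-end pipeline runs.

## What it computes

**Exploratory spatial analysis.** Global Moran's I

```
I = (n / S0) · Σᵢ Σⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ²,   zᵢ = xᵢ − x̄,
```

with a Monte-Carlo pseudo p-value `(r + 1)/(M + 1)` over M value
permutations, and its local decomposition (LISA)
`Iᵢ = zᵢ · Σⱼ wᵢⱼ zⱼ` with conditional-permutation p-values.  Areas are
classified into high-high (hot spot), low-low (cold spot), high-low,
low-high and non-significant, and cluster membership is cross-tabulated
against sociodemographic groups with chi-square tests.  Spatial weights
are queen contiguity (areas are neighbours if their boundaries share
any point), row-standardised for Moran statistics and binary for the
CAR models.

**Bayesian CAR Poisson regression.** Counts with a log-exposure offset:

```
Yᵢ ~ Poisson(Eᵢ · exp(xᵢ'β + φᵢ))
```

with either the **Leroux** prior on φ — precision
`τ⁻²[ρ(D − W) + (1 − ρ)I]`, interpolating between independence (ρ = 0)
and the intrinsic CAR (ρ → 1) — or the **localised-cluster** model
`Yᵢ ~ Poisson(Eᵢ · exp(xᵢ'β + λ_{Zᵢ} + θᵢ))`, which allocates areas to
at most G ordered intensity classes λ₁ < … < λ_G with iid residual
effects θᵢ.  Priors: N(0, 10⁵) on coefficients, Inverse-Gamma(1, 0.01)
on random-effect variances, Uniform(0, 1) on ρ, Uniform(1, 10) on the
class-penalty parameter δ.  Estimation is Metropolis-within-Gibbs;
models are compared by WAIC and convergence checked with the Geweke
diagnostic.  Coefficients are reported as prevalence ratios
(PR = exp β) with 95% credible intervals.

**Synthetic data with known truth.** A generator produces
census-like area tables on queen lattices — child populations
averaging ~1,991 (range 10–7,889), a spatially autocorrelated
deprivation score (mean 999, SD 82.5), a right-skewed Indigenous
percentage (median 2.08) — and Poisson counts from chosen β, Leroux φ
or cluster structure, so every estimator can be tested against its
generating values.

## Worked example

```python
from spatialprev import (simulate_dataset, build_weights, moran_mc,
                         local_moran, classify_lisa)

table, graph, weights, truth = simulate_dataset(rows=30, cols=30, seed=1)
w = build_weights(graph, "row_standardised")
prev = table["prevalence_pct"].to_numpy()

res = moran_mc(prev, w, n_perm=999, seed=7)
print(f"Moran's I = {res.I_obs:.3f} (pseudo-p = {res.pseudo_p:.3f})")

lisa = classify_lisa(local_moran(prev, w, n_perm=999, seed=7))
print((lisa.label == "high_high").sum(), "hot spots")
```

prints

```
Moran's I = 0.428 (pseudo-p = 0.001)
115 hot spots
```

— the simulated prevalence field is strongly spatially autocorrelated
(the pseudo-p of 0.001 is the smallest achievable with 999
permutations), and 115 of the 900 areas are significant hot spots:
high-prevalence areas surrounded by other high-prevalence areas.
`examples/04_leroux_regression.py` continues from here to the
regression stage and prints the posterior prevalence-ratio table; on
data generated with PRs (1.04, 1.10, 1.13) for the disadvantaged, most
disadvantaged and high-Indigenous groups it recovers
PR ≈ 1.04, 1.09 and 1.13 with 95% CrIs covering the truth.

The full pipeline — ingest, exclusions (areas with < 5 children,
population < 200, missing deprivation score, or no retained
neighbours), derived variables, Moran/LISA, cross-tabs, CAR models and
WAIC comparison — runs from a YAML config:

```sh
spatialprev run --config cfg.yaml --seed 11 --outdir out
```

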