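# Methods

This note documents the statistical models behind isoniche, the numerical
choices made in implementing them, what the synthetic-data generator does
and does not emulate, and the known limitations.

## 1. Data model and filtering

Input is tidy long-format CSV: one row per epidermis sample (one per
animal) and one row per scute layer per animal. δ values are per-mil
relative to VPDB (carbon) and AT-Air (nitrogen); the δ utility implements
δX = (R_sample/R_standard − 1)·10³. Lifestage is assigned from minimum
curved carapace length with a single 80 cm breakpoint (subadult strictly
below, adult at or above); adults are sexed male when the tail extends
past the carapace, otherwise female; subadults are left unsexed.

Scute filtering applies two rules, in order: recapture de-duplication
(only the earliest capture date per animal is retained; the source of the
rule does not say which copy was kept — the earliest is the natural
choice since later samples re-archive the same layers) and a minimum of
four milled layers per animal. Filtering is idempotent and every
exclusion is logged with a reason (`recapture_duplicate`, `min_layers`).
Values are parsed at full precision; rounding (2 decimals by default)
happens only at serialization.

δ values outside typical marine-consumer windows (δ¹³C ∉ [−30, −5],
δ¹⁵N ∉ [0, 20] ‰) trigger a warning but are never silently dropped;
duplicate (animal, tissue, layer) keys and lifestage labels inconsistent
with the 80 cm rule are hard errors.

## 2. Univariate niche metrics: WIC, BIC, TNW

For one isotope, the decomposition of isotopic variation into a
within-individual component (WIC), a between-individual component (BIC),
their sum TNW and the specialization index WIC/TNW is estimated two ways.

**ANOVA route.** Sequential (Type I) sums of squares for
`δ ~ layer + turtle`, fitted as nested least-squares problems; WIC is the
residual mean square, BIC the turtle mean square. With 4–18 layers per
animal the layout is unbalanced and sequential SS are order-dependent;
the order is fixed to the model formula (layer, then turtle). `layer`
enters as a numeric covariate (1 df) by default — factor coding across
animals with different layer counts is ill-defined — with
`layer_as_factor=True` available.

**Mixed-model route.** The Gaussian random-intercept model

y_ij = x_ijᵀβ + b_i + e_ij,  b_i ~ N(0, σ²_b),  e_ij ~ N(0, σ²_w)

with fixed effects (intercept, layer) and one random intercept per
animal. WIC = σ̂²_w, BIC = σ̂²_b. Estimation is by profiled REML
(default) or ML: for fixed variance ratio λ = σ²_b/σ²_w the per-animal
marginal covariance is σ²_w(I + λJ), inverted in closed form by
Sherman–Morrison (group sums only — no dense matrices), giving closed
forms for the GLS fixed effects and the scale; the profiled objective is
then minimized over log λ on [−18, 18] by bounded scalar search
(tolerance 1e−10 in log λ), with an explicit comparison against the λ = 0
boundary. Boundary estimates (σ̂²_b = 0) are flagged, not errors. REML is
the default because variance components under ML are biased downward in
the presence of fixed effects; for balanced one-way layouts the REML
maximizer equals the method-of-moments closed form
max(0, (MS_between − MS_within)/k), which the tests assert to 1e−6, and
the engine is cross-checked against an EM-REML oracle and against an
independent mixed-model implementation on unbalanced data.

The source analysis's model formula specifies a random intercept only,
while its prose mentions varying slopes; the formula is followed. A
random-slope engine is not implemented — with BIC defined as the
intercept variance it would not change the headline metrics, and the
random-intercept model is the stated estimator. TNW = WIC + BIC holds
exactly by construction for both routes; metrics are invariant to adding
a constant to all δ values and scale as c² under δ → c·δ.

## 3. Standard ellipses

For a group of n ≥ 3 points in (δ¹³C, δ¹⁵N): μ̂ = sample mean, Σ̂ =
sample covariance (n−1). The standard ellipse is the Mahalanobis c = 1
contour (≈ 40% coverage under bivariate normality), area
SEA = π√det Σ̂; SEAc = SEA·(n−1)/(n−2). A `scale` option exposes other
contour radii but all headline numbers use c = 1.

**Bayesian ellipse.** Prior: Normal–Inverse-Wishart with κ₀ = 10⁻³
(prior variance of μ is 10³·Σ — effectively flat), ν₀ = 2 (minimal proper
IW for dimension 2), Ψ₀ = I. Conjugacy gives the posterior in closed form
(κ_n = κ₀+n, ν_n = ν₀+n, μ_n, Ψ_n standard updates), so draws are exact —
Σ ~ IW(ν_n, Ψ_n), μ|Σ ~ N(μ_n, Σ/κ_n) — with no MCMC and hence no
convergence diagnostics needed. Default 10⁴ draws. SEAb is reported as
the kernel-density mode of the per-draw SEA values (Gaussian KDE,
1024-point grid between the sample extremes), with the median and a 95%
equal-tailed credible interval alongside, because point-summary
conventions differ between software. Prior-scale sensitivity is exercised
in the test suite, not in headline outputs.

**Overlap.** Ellipse boundaries are polygonized as μ + L(cos θ, sin θ)
(L = Cholesky factor, 4096 vertices by default; inscribed-polygon area
error ~4·10⁻⁷ relative), intersected by Sutherland–Hodgman half-plane
clipping (valid since both polygons are convex), and measured by the
shoelace formula. Overlap is symmetric, bounded by min(SEA₁, SEA₂), zero
for disjoint ellipses, and matches the circle-lens closed form and an
independent geometry library to the stated tolerances. A `corrected`
option inflates each boundary to SEAc scaling as an alternative
convention.

## 4. Layman community metrics

Group centroids (per-animal scute centroids within a lifestage community,
or lifestage centroids for epidermis) feed: axis ranges dNR/dCR; hull
area HA (monotone-chain convex hull, shoelace area; 0 for < 3 or
collinear centroids); CD = mean distance to the *arithmetic mean* of the
group centroids (the conventional anchor; the area-weighted polygon
centroid is available behind `hull_centroid="polygon"`); NND = mean
nearest-neighbour distance; SDNND = its sample (n−1) standard deviation.
Per-animal centroids are layer means by default; `bayesian_centroids`
switches to posterior-mean centroids, which coincide with sample means
asymptotically (the tests bound the difference at the study scale).

## 5. Size trends

Epidermis: closed-form OLS of δ on CCLmin, LRT against the intercept-only
null via the Gaussian deviance identity n·log(RSS₀/RSS₁) ~ χ²₁. Scute:
the random-intercept engine with CCLmin as fixed effect; the reported
slope comes from the REML fit, the LRT from ML refits of both models
(restricted likelihoods are not comparable across fixed-effect
structures). The size covariate is constant within animal, so the slope
is identified between animals; with ~55–100 animals the ML fixed-effect
LRT is mildly anti-conservative (measured ~4–5% at 100 balanced animals,
up to ~7% at 55 unbalanced ones) — a known finite-sample property of
χ²-calibrated LRTs, worth remembering when p-values sit near 0.05.

## 6. Synthetic-data generator

The generator emulates the *structure* of a two-tissue loggerhead study:
98 epidermis animals (53 adults, 10 of them males; 45 subadults), a
55-animal scute subset (34 adults, 6 males; 21 subadults), layer counts
from a rounded N(10, 4²) truncated to [4, 18], and CCLmin from truncated
normals per lifestage (subadults N(70, 7²) on [53.6, 80), adults
N(88, 7²) on [80, 105.8]) so labels are consistent with the 80 cm rule by
construction.

Each animal carries one latent bivariate centroid deviation
b_i ~ N₂(0, Σ_B) shared across tissues (σ_B = (1.08, 1.33) ‰ for C/N,
centroid correlation ρ = −0.30); tissue values add lifestage-specific
tissue means, a size term β_size·(CCLmin − lifestage mean) centred within
lifestage, a linear layer drift for scute (±0.02 ‰/layer), and i.i.d.
within-individual noise (scute 0.91/1.01 ‰; epidermis 0.25/0.31 ‰, the
analytical-uncertainty scale). An AR(1) option across layers exists for
robustness experiments but is off by default, matching the exchangeable-
residual assumption of the analysis models.

Calibration targets, chosen once: epidermis marginal moments ≈
(−14.54 ± 1.27, 7.64 ± 1.58) ‰ and scute δ¹³C ≈ (−16.20 ± 1.49) ‰, with
within-lifestage σ_b taken from the emulated study's per-lifestage
mixed-model components and lifestage mean contrasts sized so the pooled
between-animal variance matches its all-animals components (the pooled
random intercepts absorb lifestage contrasts when lifestage is not a
fixed effect). The emulated study's printed scute δ¹⁵N marginal s.d.
(2.13 ‰) is internally inconsistent with its own variance components
(which sum to 2.96 ‰², i.e. s.d. 1.72 ‰); the components were
prioritised, so the generator's scute δ¹⁵N marginal s.d. is ~1.74 ‰.
Size-slope defaults are the study's printed values per tissue
(epidermis +0.042/0 ‰ per cm for C/N; scute +0.031/−0.041); note these
act *within* lifestage, so marginal fitted slopes also pick up the
lifestage contrast along size.

What the generator does **not** emulate: non-normal or heavy-tailed δ
distributions, spatial/isoscape gradients, tissue-turnover kinetics,
layer-count dependence on body size, within-individual cross-isotope
noise correlation, and measurement heteroscedasticity. Passing recovery
tests therefore demonstrates estimator correctness under the models'
own assumptions, not robustness to their violation on field data.

## 7. Determinism and problem sizes

All randomness flows through `numpy.random.default_rng` seeds carried in
configs; identical config + seed gives byte-identical pipeline CSVs.
Default sizes — 10⁴ posterior draws per group, 4096-vertex overlap
polygons, 500-replicate type-I-error simulations, 200 × 10 recovery
designs — were chosen so each check is statistically decisive while the
whole suite runs in well under a minute; Monte-Carlo moment checks use
scaled-up populations (~10⁴ animals) where needed.

## 8. Known limitations

* Random-intercept only; no crossed/nested random effects, no
  heteroscedastic residuals by lifestage, no random slopes.
* The ANOVA route's BIC (turtle mean square) mixes σ²_b with layer-count
  weighted noise and is reported for comparability, not as an unbiased
  variance component — the order-of-magnitude ANOVA/LMM gap in the
  worked example is the expected signature.
* Ellipse overlap is polygonal, exact only in the vertex-count limit
  (default tolerance ~10⁻⁴ relative); overlap of SEAc-scaled boundaries
  is an alternative convention, not the headline number.
* SEAb depends on the point summary (mode vs median) at small n; both are
  always reported.
* p-values from χ²-calibrated LRTs are approximate in small samples (see
  §5).
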