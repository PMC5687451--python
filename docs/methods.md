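# Methods

This note records the models, conventions and numerical choices behind
`childmbg`, in the spirit of a model documentation page: what is assumed,
what is configurable, and what the synthetic-data tests do and do not show.

## Demographic accounting

Ages are completed months; a death at completed age *m* months is attributed
to the age bin containing *m* (neonatal = month 0, 1–11, 12–35, 36–59).
Each lived child-month is assigned independently to the five-year period of
its calendar year, so one child can contribute exposure to two periods —
the bookkeeping that synthetic-cohort period rates require. Calendar months
use the DHS-style century-month code; day-of-month is ignored. A child
alive at the interview contributes exposure only through the month before
the interview month (the interview month is incomplete). Deaths whose
month is missing cannot be placed in a bin: such records are rejected and
counted rather than silently imputed, a deliberate convention — any
imputation rule (mid-interval, random month) can be applied upstream where
the analyst can see it.

Rates are reported per 1000 livebirths; internal probabilities are
dimensionless monthly probabilities. Under-5 mortality is the
synthetic-cohort identity `1000 × (1 − Π_a (1 − q_a)^{n_a})`, with
`n = (1, 11, 24, 24)` months.

Bias ratios (external, per data source) multiply death counts, leaving
exposure unchanged — an adjustment of the empirical probability that keeps
exposure as the sample-size proxy. Whether such ratios should act on
probabilities or counts is genuinely open; the deaths-scaling convention is
this package's declared choice, with a cap at the row's exposure.

## Synthetic worlds

The generator draws, per age bin, a latent logit-scale surface

`logit q(bin, t, pixel) = logit(q₀_bin) + δ·t + Σ_c β_c x_c(t, pixel) + Z_bin(t, pixel)`

with smooth standardized covariate rasters `x_c`, a linear period trend δ,
and `Z` a separable Matérn-3/2 × AR1 Gaussian process. Defaults (50×50 grid
of 5 km pixels, 3 countries, spatial range 100 km, marginal SD 0.3, ρ =
0.8, covariate effects (−0.3, 0.2, 0.1), δ = −0.18 per period) produce
baseline under-5 mortality near 125 per 1000 declining at roughly 3–4% per
year, with neonatal rates near 35 per 1000 — levels and trends typical of
high-burden settings in the early 2000s. Baseline monthly probabilities are
(0.035, 0.004, 0.0015, 0.0008).

Admin units are a nested nearest-centroid (Voronoi-style) partition;
population is a log-normal smooth field scaled to 40 persons/km²; a
configurable fraction of pixels is labelled barren for the reporting mask.
Surveys use simple random population-proportional cluster sampling — real
surveys are stratified and weighted, a structure the generator does not
emulate, so passing tests say nothing about design-weight handling.
Mothers' ages are uniform on 15–49 and each child's birth month is uniform
over the intersection of the survey's recall window (≤ 17 years) and the
mother's reproductive span, which is what makes older mothers report older
children — the signal the SBH partition model later exploits. Child
survival is simulated month by month from the pixel-bin-period truth
(months before 1998 use the first period's truth). No migration, no
stillbirths, no age heaping.

## SBH partition model

Deaths and exposure months are each given a multinomial-logit share model
over the 16 cells with mother-age-group intercepts and a centred
survey-year covariate (ridge-stabilized multinomial logistic fit on
aggregated counts); births convert to exposure months via a per-age-group
mean exposure-per-child factor estimated from the same training pairs.
Allocation is deterministic (expected counts); sampling uncertainty is
propagated later by the geostatistical model, keeping bin-table semantics
uniform. Total allocated deaths equal total accepted children-died exactly;
cell exposures are floored at allocated deaths so the bin-table invariant
holds by construction. The model form here is a deliberate re-design of the
general idea (partition summaries using co-located complete histories)
behind a narrow interface, so alternative indirect-estimation models can be
swapped in.

## Polygon resampling

Up to *k* = 100 pixels per polygon (capped at the populated-pixel count)
are selected by deterministic systematic probability-proportional-to-size
sampling on pixel population, weighted proportionally to population;
zero-population polygons fall back to area weights with a logged warning.
Exposures and deaths split by these weights are conserved to floating-point
exactness. Full aggregated-observation (polygon-likelihood) inference is
out of scope.

## Stacked generalization

Per age bin and period, four sub-models are fit to empirical monthly death
probability with exposure weights: a binomial GAM (B-splines, 5 df per
covariate, half-event smoothing against separation), gradient-boosted trees
(depth ≤ 3, 200 trees, learning rate 0.05, subsample 0.8) on the empirical
logit, and lasso (α = 0.005) and ridge (α = 1) on standardized covariates.
Folds are spatially blocked by admin-1 when block labels are supplied,
mirroring the validation philosophy; a greedy size-balancing heuristic
assigns blocks. Predictions are clamped to (1e-6, 1 − 1e-6). A sub-model
that fails for a stratum is dropped with a warning; at least one must
survive, and the provenance manifest records which model produced each
prediction.

## Space-time binomial model

Per age bin: `deaths_i ~ Binomial(exposure_i, p_i)` with
`logit p_i = β₀ + Σ_s β_s logit(stacker_s,i) + Z(s_i, t_i)`. Fractional
exposures and deaths (from resampling and SBH partitioning) enter through
the continuous binomial log-likelihood, scaled by the row weight. Stacker
coefficients are unconstrained on the logit scale (a sum-to-one constraint
is a common alternative; unconstrained is this package's default and the
difference is absorbed by the intercept and scale of β).

`Z` is represented on a reduced-rank predictive-process basis: an 8×8 knot
grid carries weights with prior covariance `AR1(ρ) ⊗ Matérn₃/₂(range) · σ²`,
and observations load on knots through the conditional-expectation
projector. The joint mode of (β, knot weights) is found by penalized IRLS
with backtracking line search; β carries a weak N(0, 10²) prior that keeps
the Hessian positive definite under collinear stackers. Hyperparameters
(range, σ, ρ) maximize the Laplace-approximate marginal likelihood over a
coarse grid (ranges scaled to the domain diagonal) refined by a Nelder-Mead
polish — empirical Bayes. Candidate maps are joint Gaussian draws of
(β, weights) at the mode mapped through the pixel-level projector, so draws
are spatially coherent; hyperparameter uncertainty is *not* propagated,
which slightly understates total uncertainty (the cross-validation coverage
check bounds the practical effect). A memory guard refuses draw arrays
beyond a configured budget rather than silently thrashing.

Age bins are fitted independently; joint modelling across bins and
spatially varying coefficients are out of scope.

## Post-processing

Candidate maps convert draw-wise to 5q0/NMR; admin aggregates are
population-weighted means of pixel rates per draw (total population by
default; an under-5 population raster can be supplied instead). Raking
multiplies every draw's pixels by the country-period ratio
reference / model-posterior-mean on the rate scale, then clips to
[0, 1000] with a warning — the unclipped procedure makes post-raking
national means equal the reference identically, and tests check closure to
1e-6 relative. 5q0 and NMR are raked independently; in extreme cases raked
NMR could exceed raked 5q0, and a warning is the guard, not a constraint.
Uncertainty intervals are equal-tailed 2.5/97.5% quantiles of draws. The
reporting mask removes pixels with barren land cover or population density
below 10 persons per km² (density computed from pixel population over pixel
area).

## Trends

Annualization is continuous: `AROC = ln(r_start/r_end)/years`, positive for
decline. This convention makes a two-thirds reduction over 25 years print
as 4.4% per year (the discrete convention would print 4.3%), matches the
projection identity `r_2030 = r_2015·exp(−AROC·15)` exactly, and makes
`project` and `required_aroc` exact inverses. Period point estimates for
2000 and 2015 anchor the 15-year window with no mid-period offsets. All
trend statistics are computed per draw and summarized afterwards; a test
confirms the draw-first path differs from (and is used instead of) the
summary-first shortcut.

## Validation

Spatial folds assign whole admin units (level 1 or 2) to five folds
balancing total exposure (greedy longest-processing-time). Cluster-level
coverage uses posterior-*predictive* intervals — a latent draw pushed
through a binomial at the observed exposure — because latent-rate intervals
cannot cover noisy small-count cluster data at the nominal level. Death
counts per cluster observation are small integers, so a raw 95% count
interval over-covers structurally; coverage is therefore scored through the
randomized probability integral transform of the observed count under the
predictive distribution, which is uniform under a calibrated model and
makes the nominal level exactly attainable. Admin-level agreement is
exposure-weighted Pearson correlation of predictions and observations
pooled within units.

## Problem sizes and defaults used in the reproduction script

The reproduction script (`scripts/acceptance.py`) uses the package's
desk-scale study conditions: the default 50×50-pixel world; 2000 clusters
at exposure 500 child-months per cell for the planted-coefficient study; 20
replicates of 800 clusters on a 40×40 grid for range recovery (truth:
range 100 km, σ 0.4, ρ 0.8); a 500-cluster survey for the five-fold
calibration study (stacking restricted to the linear sub-models, 250
posterior draws); ~20 000 mothers for the summary-birth-history round trip;
and 100 draws for the raking-closure pipeline. These sizes were chosen so a
full reproduction completes in minutes on one CPU while keeping Monte-Carlo
error well inside the tolerances being checked.

## Known limitations

- Empirical-Bayes hyperparameters: no hyperparameter uncertainty in the
  candidate maps.
- The predictive-process basis attenuates fine-scale variance below the
  knot spacing; with the default 8×8 knots and ranges well above the knot
  spacing the attenuation is small, but short-range worlds need more knots.
- The SBH partition model is a re-designed stand-in for the general
  approach, not a reimplementation of any specific published variant.
- Survey design weights, age heaping, displacement of cluster GPS
  coordinates, and migration are not modelled in the generator, so the test
  suite is silent about their effects on real data.
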