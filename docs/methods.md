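# Methods

## Model

Expected absolute fitness (fruit count `W`) of plant `j` is modeled as a
Poisson response with log link:

```
log E[W_j] = alpha + year(j)
           + sum_i f_i(z_ij)            (5 trait smooths)
           + sum_k g_k(e_kj)            (3 environment smooths)
           + sum_{i,k} t_ik(z_ij, e_kj) (15 interaction tensors)
           + s(lon_j, lat_j)            (spatial smooth)
```

Traits are the number of leaves, branches and stems, the mean internode
distance (mm) and height (cm); environments are substrate type (ordinal
1–4, entered as a continuous covariate), vegetation coverage (%) and
conspecific density (count within 1 m). Substrate as continuous inherits
the usual caveat: only a linear trend in soil content is identifiable,
no contrasts between individual substrate classes.

### Bases and penalties

* Univariate smooths: cubic B-splines, default dimension `k_main = 9`,
  interior knots at quantiles of the unique covariate values, penalty
  the exact integrated squared second derivative (Gauss–Legendre per
  inter-knot interval; the integrand is piecewise quadratic so this is
  exact). Each smooth carries a sum-to-zero constraint over the training
  rows, absorbed via an orthonormal null-space reparameterization.
* Interaction smooths: tensor products of two marginal cubic bases
  (default 5 × 5) with one penalty per margin. Both margins are
  marginally centered (sum-to-zero) before the tensor is formed, and the
  resulting block carries one further overall sum-to-zero constraint, so
  the tensor spans interaction-only functions and the design is
  structurally full column rank; a main-effect smooth plus its centered
  tensors jointly represent the full tensor-product surface for that
  trait–environment pair. This is the standard
  main-effects-plus-interaction decomposition of a full tensor smooth;
  without it the marginal subspaces of the tensors would be exactly
  collinear with the main effects and jointly unpenalized. One
  data-driven caveat: a covariate whose upper levels hold only a
  handful of plants (conspecific density, typically) cannot support the
  full product space across five traits, so the realized design can be
  numerically rank deficient there; the curvature penalties and the
  stabilizing ridge resolve those directions, exactly as penalized GAM
  software conventionally does.
* Spatial smooth: a full 5 × 5 tensor of longitude and latitude with a
  single overall sum-to-zero constraint. Coordinates are used as given
  (decimal degrees); the marginal bases absorb the anisotropic degree
  scaling.
* A covariate with fewer unique values than the requested basis
  dimension gets its dimension reduced automatically (with a logged
  warning); substrate always reduces to 4.

### Fitting

Penalized IRLS maximizes the penalized Poisson log-likelihood,
monitoring the penalized deviance with step-halving (tolerance 1e-8
relative change, max 200 iterations, linear predictor clipped at ±30).
The system is solved in a column-equilibrated parameterization
(unit-RMS columns) with a tiny stabilizing ridge (1e-8 · n on the
equilibrated scale, configurable); results are mapped back to the
original basis. The coefficient covariance is `(X'WX + S_lambda)^-1`
(the Bayesian posterior covariance of the penalized fit).

Smoothing parameters are selected by a Fellner–Schall fixed-point
iteration (the standard update targeting the REML gradient condition),
one parameter per penalty (univariate smooths: 1; tensors: 2), starting
from a scale-balanced value (`lambda_j tr(S_j) = tr(X'X_j)`), with
update factors clipped to [1/8, 8], lambdas kept within 1e±6 of their
balanced scale, and at most 60 outer iterations. Alternatives: `gcv`
(one common multiplier optimized by bounded scalar search) and `fixed`.

## Gradient estimands

All gradients are sample-averaged derivatives of predicted relative
fitness `w(x) = W(x)/Wbar`, where `Wbar` is the mean *model-predicted*
fitness over the sample (keeping the gradients a pure functional of the
surface; the observed-mean alternative differs by O(residual mean)).
Derivatives are central finite differences with step `1e-4 ×` the
covariate's sample SD; mixed partials use the 4-point cross stencil.
Each individual's non-focal covariates (including environments, year
and location) stay at their observed values; standardization is by
sample SDs (σ_i for β, σ_i² for γ, σ_i·σ_k for the ecological
gradients — the scaling record is attached to every result so the
σ_z-only convention is recoverable). The quadratic gradient is reported
as the averaged second derivative itself, **without** the factor-of-two
doubling used in some regression conventions; the classical-regression
module reports `2 ×` its fitted quadratic coefficient so the two are
directly comparable, and they coincide exactly on an identity-link
globally quadratic surface.

Finite-difference accuracy: halving the step changes gradients by less
than 1e-6 relative (the step sits in the asymptotic regime; the
exp-form evaluation of perturbed linear predictors avoids catastrophic
cancellation in the second differences).

## Parametric bootstrap

Each replicate draws new fruit counts from the fitted Poisson means at
the observed covariates, refits the surface and recomputes all
gradients. Replicate refits re-estimate the smoothing parameters
(warm-started from the original fit, a short Fellner-Schall run) —
holding them fixed would wipe out the smoothing-selection component of
uncertainty, which dominates the sampling variability of the quadratic
gradients; a fixed-smoothing refit remains available via
``refit_response(..., reselect_smoothing=False)``.
SE = replicate standard deviation. Two-sided p-value against the null
value 0: `2·min(#{rep ≥ 0}+1, #{rep ≤ 0}+1)/(n_boot+1)`, capped at 1,
computed over completed replicates (non-converging replicates are
dropped and counted; more than 20% dropped aborts). A fast
`coefficient` option resamples coefficients from the Gaussian posterior
instead of refitting.

## Synthetic-population generator

The generator emulates the statistical structure the analysis assumes:

* **Extent and locations:** a 125 m × 60 m rectangle (7500 m²); plant
  locations from a Thomas cluster process (parent intensity 0.07 /m²,
  offspring SD 1 m), giving realistic aggregation and a mean 1-m
  neighbor count near 2 at study-scale n.
* **Environments:** substrate and vegetation derive from latent
  stationary Gaussian random fields (low-rank random-Fourier
  approximation, Gaussian covariance, length scales 8 m and 6 m);
  substrate by thresholding at quartiles into {1,2,3,4}, vegetation by
  probability-integral transform to 0–100% rounded to the nearest 10%.
  Conspecific density is *recomputed from the generated coordinates*
  (1-m radius), never drawn independently.
* **Traits:** a Gaussian copula with modest positive correlations among
  size traits (0.2–0.4) feeding negative-binomial marginals for counts
  (means 82 leaves, 14 branches, 2 stems; dispersions 3, 3, 2) and
  log-normal marginals for internode (mean 16.1 mm, CV 0.30) and height
  (mean 37.34 cm, CV 0.35). Centers are the study population's reported
  means; dispersions and correlations are package defaults chosen for
  realistic right-skewed distributions, not field estimates. An
  optional trait–environment coupling (off by default) shifts trait
  latents by the environment fields, for testing that direct
  environmental terms absorb environmentally induced trait–fitness
  covariance.
* **Fitness:** Poisson with
  `log mu = a + Σ b_i (z_i − m_i) + Σ c_i (z_i − m_i)² + Σ d_k (e_k − m_k)
  + Σ g_ik (z_i − m_i)(e_k − m_k) + year + spatial`, year effects
  {2015: 0, 2016: +0.3} and a smooth spatial field (amplitude 0.3,
  length scale 20 m) by default. Default effect sizes (per nominal SD:
  β-scale −0.09, 0.06, 0.20, −0.12, 0.35 for the five traits; quadratic
  0.05 on leaves and height; environment −0.18, −0.04, −0.12;
  interactions −0.08 to 0.08 plus height × substrate −0.10) were chosen
  once to mirror the sign structure of selection reported for this
  system at moderate magnitude, subject to the fitness distribution
  staying realistic for fruit counts (mean ≈ 13, SD ≈ 23, max a few
  hundred).
* **Ground truth:** `true_gradients` evaluates the exact analytic
  derivatives of the generating relative-fitness function at the
  realized sample (Monte-Carlo averaging over the same individuals the
  estimator averages over), so estimator and truth share the averaging
  measure.

What the generator does **not** emulate: overdispersion or
zero-inflation of fruit counts beyond the surface-induced kind,
measurement error in traits or coordinates, multi-year survival
(exactly one record per individual), pollination/pedigree structure,
and trait–environment confounding by default. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to their violation.

Simulated coordinates are planar meters mapped to pseudo-lon/lat by a
declared equirectangular affine around (2.99°E, 43.11°N) — exact at the
~100 m scale — so the same lon/lat code path is exercised end to end;
`xy_meters()` inverts it with the same constants.

## Spatial utilities

Density uses a k-d tree (O(n log n)), validated against the O(n²)
distance matrix. Moran's I uses inverse-distance weights with a 1 cm
distance floor by default (binary-radius optional); inference by value
permutation over locations (two-sided with the +1 correction) or the
closed-form randomization variance. The Moran test defaults to raw
fruit counts.

## Validation-suite problem sizes

The statistical acceptance checks run at the package's validation
defaults: parameter recovery over 8 synthetic populations of n = 2000
with 40 bootstrap replicates each (basis dimensions 5/4/6 for
main/interaction/spatial smooths — the generating surface is quadratic,
well inside this span; the population size matters, since the
quadratic gradients carry smoothing-shrinkage bias at a few hundred
plants that only becomes small relative to the bootstrap SE at study
scale); bootstrap calibration over 30 no-selection
populations of n = 400 with 50 replicates each, against the exact
binomial 95% acceptance band for that replicate count; classical
equivalence, zero-gradient identities and the spatial oracles at the
sizes stated in the tests.

## Known limitations

* The quadratic gradient γ of relative fitness on a log-link surface
  contains a `mean w·(dη/dz)²` term. Near a flat surface this makes the
  bootstrap replicates of γ almost surely (small) positive — replicate
  refits see data simulated from the already-smoothed fit, so their
  curvature is suppressed and the squared-slope term dominates — and
  the sign-based p-value against a point null of zero then over-rejects
  badly (empirically ~50% at n = 400 and still 10–40% at n = 1000, for
  both the resimulation and the posterior-coefficient bootstrap). This
  is a structural property of the estimand + sign-test combination, not
  of a particular implementation; γ p-values near zero curvature should
  be read with this in mind, and the calibration test documents the
  failure rather than hiding it. The linear, environmental and
  ecological gradients do not share this structure and calibrate
  correctly.
* Parameter recovery is not uniformly inside two bootstrap SEs. Across
  replicate study-scale populations (n = 2000) roughly 25 of the 28
  standardized gradients recover their generating values with
  several-fold margin, but the entries carrying the strongest effects
  (height's quadratic and interaction terms) and those confounded with
  the residual smooth spatial fitness field (substrate- and
  density-linked terms; both environments are themselves spatially
  structured) show bias of about 1.0–1.4× the 2-SE yardstick: REML
  shrinkage biases the largest curvature/interaction components toward
  zero faster than the bootstrap SE shrinks with n, and a finite
  spatial basis can never fully separate a smooth spatial fitness
  field from spatially autocorrelated environments. Diagnostics:
  removing the generator's spatial field eliminates the
  substrate/density biases but not the shrinkage ones; the failing set
  shifts with the spatial basis dimension while its size stays 2–4.
  Both mechanisms are properties of penalized-spline selection
  analysis on this study design, and the recovery test reports them
  rather than hiding them.
* Exact reproduction of results fitted with other GAM software will
  differ in the second decimal when basis dimensions, identifiability
  constraints or smoothing criteria differ; these were not reported for
  the original analyses of this system, so the defaults here are
  documented package choices.
* No negative-binomial or zero-inflated families; no trait × trait
  interaction tensors; no canonical rotation of γ.
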