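# Methods

## Size proxy and its conventions

A genus is represented by one calyx biovolume for its entire
stratigraphic range, on the convention that the holotype of the type
species is representative of the genus throughout its duration. Biovolume
is estimated from a geometric solid fitted to the calyx — cylinder, cone,
frustum, sphere, hemisphere, ellipsoid or hemi-ellipsoid — using the
closed-form volume of that solid in mm³. The seven-solid list is a
package choice covering the conical, bowl-shaped and globular calyx
morphologies of Palaeozoic crinoids.

Sizes are analysed as **log₁₀ mm³**. The base is a documented package
convention: every downstream statistic is linear in the choice of log
base, and the extinction/origination decomposition identity is base-free,
so only the absolute scale of reported values depends on it.

## Time binning

The time axis is the packaged ICS-style Ordovician–Permian stage table
(Tremadocian → Changhsingian, 38 stages; editable CSV). Stage assignment
is by name only (sub-stage qualifiers are collapsed to the stage), and the
numeric time axis uses stage midpoints, (base + top)/2 Ma; elapsed time in
a series is Myr since the first included stage's midpoint. A genus
contributes its single size to **every** stage its range intersects
(range-through with constant size); this convention is forced by the
one-value-per-genus rule and is what makes the boundary decomposition's
bookkeeping exact.

Per-bin statistics are the unweighted mean, the unbiased sample variance,
and the genus count. Singleton bins have no sample variance; the pooled
within-bin variance of the series (weights nᵢ − 1) is substituted and the
bin flagged, because the likelihood machinery requires a finite
sampling-error term εᵢ = varᵢ/nᵢ in every bin. Error bars reported by the
series builder are standard errors, √(varᵢ/nᵢ); the choice of SE over SD
is a documented convention.

The two "pruned" between-extinction windows default to
Rhuddanian→Givetian and Tournaisian→Changhsingian and are configurable.

## Evolutionary-mode models

All nine models treat the vector of bin means as a single multivariate
normal observation (joint parametrization) and add εᵢ to the covariance
diagonal. Parameters: ancestral state a, step mean μₛ (per Myr), step
variance σ²ₛ (per Myr), stasis optimum θ, stasis variance ω, and for
two-regime models a shift index reported as the first stage of the second
regime.

Numerical strategy: the variance parameter (σ²ₛ or ω) is profiled on a
log scale — a coarse scan (~30 points spanning 22 log-units below to 6–8
above a method-of-moments start) followed by bounded Brent refinement —
with the mean parameters solved in closed form by GLS at every step via a
Cholesky factorization. The ω → 0 boundary is evaluated exactly, so
Stasis degrades gracefully to StrictStasis. Nested models feed their
optima into the richer model's candidate set (URW → GRW, whole-series
Stasis → each Punc-1 segment), which makes the log-likelihood nesting
orderings hold by construction rather than by optimizer luck. This
profile-likelihood design replaces a generic multi-start quasi-Newton
search: the profiles are one-dimensional and cheap, need no random
restarts, and are deterministic.

Two-regime models fit the segments independently with elapsed time
restarted at the shift; the second regime's level is a **free parameter**,
not anchored to the first regime's endpoint — the simplest defensible
convention, recorded here because the alternative (anchored) changes K and
the likelihood. K counts the shift point: K = K₁ + K₂ + 1 (so Punc-1 has
K = 5). The minimum segment length `minb` defaults to 5 bins and is
recorded in CLI output; series shorter than 2·minb bins are compared over
the four simple models only, with weights renormalized over that set.
Akaike-weight ties break toward fewer parameters, then canonical model
order.

A numerical floor of 1e-10 (log₁₀ mm³)² is applied to εᵢ so that
noise-free synthetic series (ε = 0, elapsed time starting at 0) keep the
joint covariance positive definite. The floor is shared by all models, so
AICc comparisons remain fair.

## Extinction/origination decomposition

At the boundary from stage S to its successor, cohorts are: extant
(range includes S), victims (last stage = S), survivors (extant minus
victims), originators (first stage = successor). The components are
survivor mean − extant mean (extinction) and next-stage mean − survivor
mean (origination); they sum to the total change to machine precision
because the next-stage cohort is exactly survivors ∪ originators, each
genus with one constant size. A boundary with zero survivors has no
survivor mean: both components are NaN with an explicit flag rather than
silently zero, while the total change remains defined. A boundary with no
turnover at all reports exact zeros.

Selectivity is summarised as mean(victims) − mean(survivors) (> 0 ⇒
larger genera preferentially died) with a two-sample K-S test. K-S
statistics and asymptotic two-sided p-values come from
`scipy.stats.ks_2samp`; interval letter groups connect pairs with
p > α (α = 0.05 default) and letter connected components in input order.
No multiple-testing correction is applied by default (a Bonferroni flag
exists but is off), mirroring common practice for these pairwise
displays.

## Climate regression

The GLS model is yₜ = β₀ + β₁xₜ + eₜ with AR(1) errors, estimated by
exact maximum likelihood (not REML, so AICc is comparable across mean
structures): for fixed φ, the Prais–Winsten transform reduces the model
to OLS, β and σ² drop out in closed form, and the scalar profile
likelihood is maximized over φ ∈ (−0.999, 0.999) with φ = 0 evaluated
explicitly (so AR1 never scores below AR0). |φ̂| > 0.98 raises a
nonstationarity warning. K counts β₀ (+β₁), σ², and φ for AR1; the fit
requires n ≥ K + 2 so the AICc correction is defined. Predictor and
intercept-only null are compared pairwise by AICc under the same error
structure.

Proxy curves are consumed as (age Ma, value) tables; a stage's value is
the mean of curve samples within its age span (for a locally linear curve
this equals the midpoint value). δ¹⁸O-style inverse proxies enter through
a sign flip. Detrending defaults to first differences of both variables —
the standard guard against spurious trend–trend correlation in palaeo
time series — with a linear-residual mode as the alternative; which
variable the differencing is applied to (both) is a package convention.

## Synthetic data generator

`simulate_genus_table` emulates the structure of the compiled genus
database: per stage a Poisson(26) number of genera originate (≈ 1,000
genera across 38 stages), each drawing a clade from a
camerate/pentacrinoid mix (0.35/0.65, pentacrinoids split
Disparida/Cladida/other) and a log-size from its subclass's normal
distribution (Camerata N(0.5, 0.8²), Pentacrinoidea N(−0.1, 0.8²) in
log₁₀ mm³ — camerates the larger clade, overall values on the order of
the empirical stage means). Each extant genus dies each stage with
probability expit(logit(p_base + pulse) + β·(size − clade mean)), with
p_base = 0.4; the defaults include size-selective pulses (extra
probability 0.3 and 0.25, β = 1) at the Katian and Givetian, emulating
the late Ordovician and late Devonian extinction intervals. With β = 0
extinction is size-neutral by construction, which the calibration tests
exploit. A single seeded generator drives all draws; a fixed seed gives
identical tables.

What the generator does **not** emulate: preservation and sampling
failure (every simulated genus is observed over its true range),
within-genus size change, phylogenetic autocorrelation of size beyond the
two-level clade means, and stage-duration-dependent turnover. Passing
tests therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to the sampling biases of real
occurrence data.

`simulate_trait_series` draws exactly from the generative processes the
likelihood models assume (walk increments N(μₛΔt, σ²ₛΔt); stasis draws
N(θ, ω)) plus observation noise N(0, ε), with per-bin variance and count
set so varᵢ/nᵢ = ε. `simulate_climate_curve` provides ramp, sine and
random-walk proxy curves on a 1-Myr age grid.

## Problem sizes used by the test and acceptance runs

Chosen as the package's own verification design: worked-example
decompositions use the published cohort counts (55/43/12/4 and
75/55/20/46) with mean-preserving scatter; the additivity identity is
checked on 200 seeded random tables; drift/stasis parameter recovery uses
2,000- and 200-bin series; model-selection calibration uses 100
replicates per generator at 40 bins; the size-neutral null calibration
pools all boundaries of 200 tables of roughly 750 genera; grid-search
oracles run on 12-bin series.

## Known limitations

* Genus ranges are taken at face value; no confidence intervals on
  stratigraphic ranges or sampling standardization.
* The nine-model family excludes OU and covariate-tracking models, and
  model-averaged parameter estimates are not produced.
* The shift point in two-regime models is restricted to one change and
  counted as a full parameter in K; other conventions exist and would
  shift AICc by a constant per model.
* Stage bins are uneven in duration; all models absorb this through the
  midpoint time axis, not through duration-dependent sampling error.
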