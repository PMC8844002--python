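# Methods

## The choice model

`pathshade` models a pedestrian's binary path choice as cost minimisation
with logistic noise. A path option decomposes into sun-lit, tree-shaded and
building-shaded metric stretches `(a_sun, a_tree, a_shade)`; its perceived
cost for participant *j* is

    c = β_j [a_sun + (1 − ρ) a_tree] + a_shade + ρ a_tree.

β_j multiplies the *effective* sun-exposed length; ρ splits tree shade into
a sun-like part (weight 1 − ρ) and a building-shade-like part (weight ρ), so
100 m of tree shade at ρ = 0.5 behaves like 50 m of sun plus 50 m of full
shade. At β = 1 the ρ terms cancel and cost equals total length — a useful
algebraic identity that the test suite exercises as an invariant. The choice
probability is p(A) = 1/(1 + exp(Δc/τ_k)), where Δc = c(A) − c(B) and τ_k is
a per-choice-set temperature: the two choice sets of the courtyard design
differ systematically in how large their cost gaps are, so a shared τ would
conflate decisiveness with option geometry.

Assumptions worth keeping in mind: decisions are independent across trials
(no order, fatigue or heat-accumulation effects), β_j is static within a
session, and no covariates (weather, gender, aesthetics) enter the utility.

### Priors and parameterisation

    d, e ~ Normal(0, 1)
    β_j  ~ Gamma(shape = exp(d + e), rate = exp(d − e))
    τ_k  ~ Gamma(12.5, 50)        (shape/rate)
    ρ    ~ Beta(1, 1)

The (d, e) hyperparameterisation decorrelates the Gamma's shape and rate
(their product and ratio move on orthogonal axes), which is what lets a
gradient-based sampler move through hyperparameter space without the strong
shape–rate ridge of the naive parameterisation. The conditional prior mean
of β_j is exp(2e).

Two documented quirks:

* The τ prior is Gamma(12.5, 50) under the shape/rate convention, whose mean
  is 12.5/50 = **0.25**, although the prior is sometimes described as having
  mean 0.2 (which would require, e.g., Gamma(10, 50)). This package
  implements Gamma(12.5, 50) as printed. Under shape/*scale* the mean would
  be an absurd 625 on the scaled length axis, so shape/rate is the only
  sensible reading.
* All lengths are multiplied by 0.01 (hectometres) before the likelihood, so
  a typical 20 m option-length difference sits at 0.2 — the scale the τ
  prior is built for. Because the cost is linear in lengths, scaling the
  inputs and scaling Δc are equivalent; this implementation scales the
  composition differences once, inside the likelihood builder
  (`pathshade._posterior`), and `LENGTH_SCALE` is the single configuration
  constant.

### Population-level β

"The population β" can mean two things, and the package computes both:

* **pooled** (the default): concatenate the posterior draws of every
  participant's β_j — the posterior of the population distribution of β,
  whose spread includes between-participant variation;
* **hyper**: the posterior of exp(2e), the prior mean of the population
  distribution — a tighter summary of the population centre.

On synthetic data at the default scale the two means agree to ~0.01.
`PathChoiceResults.population_beta(method=...)` selects; reports emit both.

## Sampling

The posterior is explored by a No-U-Turn Hamiltonian Monte Carlo sampler
written for this package (`pathshade._nuts`): multinomial trajectory
sampling over a doubling tree, dual-averaging step-size adaptation to a
0.8 target acceptance, a diagonal metric estimated in Stan-style expanding
warmup windows, and divergence detection at an energy error of 1000 nats.
The log posterior and its gradient (`pathshade._posterior`) are analytic —
the only special functions involved are digamma terms from the Gamma
hyperprior — and are verified against finite differences in the test suite.
Sampling runs on the unconstrained scale (log β_j, log τ_k, logit ρ) with
the corresponding Jacobians.

Defaults follow the published estimation settings: 4 chains, 2000 tuning
steps, 10000 draws per chain. On a 552-decision cohort this takes about
80 s on one CPU and reaches a minimum bulk ESS above 5000 with max
rank-normalised R-hat ≈ 1.0005 and no divergences. A run with more than
0.1% divergent post-warmup transitions is flagged (`RuntimeWarning`, plus
`PathChoiceResults.flagged`). Diagnostics (rank-normalised split R-hat, bulk
ESS) are computed by `arviz`. Note that bulk ESS of antithetic NUTS chains
can legitimately exceed the raw draw count.

## Scene shading

The geometric front end reproduces a ray-grid shading calculation:

* **Sun position** from a NOAA-style low-precision ephemeris (Meeus
  equations: equation of centre, apparent longitude, corrected obliquity,
  equation of time), accurate to well under 0.5° for 1950–2100, with NOAA's
  refraction correction. Naive timestamps are rejected outright — a wrong
  implicit timezone moves the sun tens of degrees.
* **Ray casting**: each strip polygon is sampled at the cell centres of a
  global axis-aligned 0.1 m lattice (anchored at the origin so results are
  bit-reproducible and independent of bounding boxes). One ray per point is
  shot toward the sun. A ray entering a building's vertical extrusion —
  tested as a 2D segment/footprint intersection over the horizontal run
  `height/tan(elevation)` — counts as building shade; otherwise a positive
  ray-parameter intersection with a tree-crown ellipsoid counts as tree
  shade. Buildings take precedence over trees: a building blocks light
  completely, a crown only partially.
* **Wide paths** are represented by 5 strips of 1.2 m; the strip with the
  lowest sun fraction is the path's representative composition (ties break
  to the lowest strip index — the convention is arbitrary but fixed).
  Building shade under 15% of a wide path (under 0.9 m of a 6 m path) is
  reassigned to sun: too thin a sliver to walk in.
* Fractions × centreline length give the metric composition. Conservation
  (fractions sum to 1) is enforced by the `ShadeFractions` type itself.

Grid error for a straight shadow edge is at most one grid cell on each side
of the edge, i.e. `2·grid_step/strip_width` in the fraction — the bound the
oracle tests use against the analytic single-wall shadow depth.

Tree crowns are ellipsoids (the simplest parametric convex hull); real
crowns are irregular, so compositions computed for a real site will deviate
from any rendered-scene ground truth in the tree-shade component.

## Synthetic data

`pathshade.simulate` generates whole experiments with the structure the
model assumes: 46 participants × 13 trials by default (one designated test
trial per participant whose dominated option is ≥1.5× longer and ≥2×
sunnier — margins chosen as clearly noticeable dominance), two choice sets
split half/half across the cohort, option lengths 40–250 m with 5–40 m
length differences (averaging ~20 m), 70% sun/distance trade-off trials and
30% dominance trials (verified by construction at ρ = 1), β_j drawn from
the model's own Gamma population with mean 1.16 and standard deviation 0.2
(a moderately sun-averse cohort with most individuals between ~0.8 and
~1.7), ρ = 0.5, τ = 0.2 for both sets, and Bernoulli outcomes from the
logistic rule. The non-sun remainder of each option is split uniformly
between tree and building shade. A 200-participant "recovery scale" exists
because 13 trials per participant deliberately under-identify individual
β_j.

What the generator does *not* emulate: sequential dependence between trials,
sun-state dynamics within a session (all trials default to full sun),
participant dropout, coder noise, or spatial correlation between the two
options' compositions (real options share a scene). Passing recovery tests
therefore show that the estimator works *under the model's own assumptions*,
not that the model is correct for any particular site.

### What is and is not identifiable

Simulation at the recovery scale (200 × 13) shows:

* τ_k and the population-mean β recover within ±0.1 essentially always;
* ρ is intrinsically weakly identified near β ≈ 1: its likelihood leverage
  is ∂Δc/∂ρ = Δa_tree·(1 − β_j), which vanishes as β_j → 1. With the
  generator's population centred at 1.16, the sampling distribution of the
  ρ posterior mean has a standard deviation near 0.09 (and the posterior is
  well calibrated — its spread honestly reports this uncertainty), so a
  ±0.1 recovery band captures only ~70–75% of replicates. At the 46 × 12
  study scale the ρ posterior is wider still. This is a property of the
  design, not of the sampler; cohorts with stronger sun aversion or larger
  tree-shade contrasts between options identify ρ much faster.

## Event processing and eligibility

The observational pipeline mirrors a video-coding protocol: chronological
event logs per participant (decision / end-of-trial / sun-presence /
sun-exposure / water-intake), row-level validation with an explicit error
report (nothing is silently dropped), cross-coder comparison that flags
pairs differing in decision label, sun-presence state, or by strictly more
than 5 s in time, and treatment flagging by the most recent prior
sun-presence event ("sun present" defaults to {full_sun, cloudy_sun} — both
cast visible shadows — and is configurable). Eligibility filtering drops the
designated test trial everywhere, excludes participants who chose its
dominated option (machine-readable reason `failed_test_trial`), keeps
zero-treatment participants in the counts but out of the model, and is
idempotent. Which trial is the test trial is a required configuration value,
not a constant.

## Numerical choices and degenerate inputs

* Logistic probabilities use `expit`/`logaddexp` throughout; extreme cost
  gaps saturate to 0/1 without overflow.
* Strict inequalities define trade-off vs dominance classification; exact
  ties in both length and effective sun are "indifferent".
* Reported metre equivalences round to whole metres; internal computation is
  unrounded, and the identity `fixed_shade + β·s = shade_target` holds
  exactly before rounding.
* Zero-grid-point strips, night-time shading requests, naive timestamps,
  non-positive β/τ, out-of-range ρ, and missing outcomes raise errors that
  name the offending field.
* Fits are reproducible end to end given a seed (per-chain child seeds are
  spawned from one `SeedSequence`); identical seeds give identical draws.

## Problem sizes used in the shipped checks

The test suite fits reduced-but-honest configurations chosen for a laptop
budget: the full published settings (4 × 2000 + 10000) on the 46 × 12
cohort for the sampler-health check (~1.5 min), five 200 × 13 replicates at
2 chains × (500 + 800) for recovery (~2 min total), and 2-chain fits of a
few hundred draws for API tests. `scripts/acceptance.py` runs the full
published settings. The refit of the study's deposited dataset
(`tests/test_acceptance.py::test_real_data_refit_reproduces_published_posterior`)
requires a local copy of the deposit at `data/osf_decisions.csv` and fails
with an explanatory message when it is absent.

## Known limitations

* ρ recovery at ±0.1 is not reliably attainable at the default generative
  conditions (see identifiability above).
* The shading model ignores penumbra, diffuse radiation and vegetation
  porosity; crowns are solid ellipsoids.
* The solar ephemeris is topocentric-geometric plus refraction; it does not
  model local horizon obstruction beyond the scene's own geometry.
* The CLI stores posteriors as NetCDF (via h5netcdf); very large draw counts
  (>10⁶ per parameter) would be better served by a chunked store.
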