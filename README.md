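# pathshade

Pedestrians in hot cities trade walking distance against sun exposure: given
two ways to reach a target, many will accept a longer path if more of it is
shaded. `pathshade` is a Python package for quantifying that behaviour from
two-alternative path-choice experiments. It is aimed at researchers in urban
climate, pedestrian behaviour and spatial cognition who need to (i) compute
the sun/tree-shade/building-shade composition of path options from simple
2.5D site geometry and the sun's position, (ii) fit a hierarchical Bayesian
choice model to binary path decisions, and (iii) simulate whole experiments
to check what such designs can and cannot identify.

## The model

Each path option decomposes into metric stretches walked in the sun
(`a_sun`), under tree shade (`a_tree`) and under building shade (`a_shade`).
The perceived cost of an option for participant *j* is

    c = β_j · [a_sun + (1 − ρ) a_tree] + a_shade + ρ a_tree

where `β_j > 0` is the participant's distance-inflating coefficient of the
sun (β > 1 means walking in the sun feels longer than it is) and
`ρ ∈ [0, 1]` is the perceived tree-shade intensity: ρ = 1 makes tree shade
equivalent to building shade, ρ = 0 makes it equivalent to full sun. The
probability of choosing option A over B in choice set *k* is logistic in the
cost difference Δc = c(A) − c(B):

    p(choose A) = 1 / (1 + exp(Δc / τ_k))

with a per-choice-set temperature `τ_k`. Participants are partially pooled
through a Gamma population distribution with a decorrelating hyperprior:

    d, e ~ Normal(0, 1)
    β_j  ~ Gamma(shape = exp(d + e), rate = exp(d − e))   # prior mean exp(2e)
    τ_k  ~ Gamma(12.5, 50)
    ρ    ~ Beta(1, 1)

Lengths enter the likelihood in hectometres (×0.01). The posterior is
sampled with a built-in No-U-Turn Hamiltonian Monte Carlo sampler using
analytic gradients; convergence is checked with rank-normalised R-hat and
bulk effective sample size (via `arviz`).

The geometric front end mirrors how such experiments are parameterised: path
strips are sampled on a 0.1 m grid, one ray per grid point is cast toward
the sun (a NOAA-style ephemeris provides azimuth/elevation), buildings are
extruded footprints, tree crowns are ellipsoids, wide paths are five 1.2 m
strips of which the sunniest-avoiding ("lowest sun fraction") strip is
representative, and building shade covering under 15% of a wide path is
discarded as unusable.

## Worked example

```python
from pathshade import PathChoiceModel, SimulationConfig
from pathshade.simulate import simulate_study
from pathshade.report import headline_numbers

# a synthetic cohort with the study's structure: 46 participants x 13 trials,
# true rho = 0.5, tau = 0.2, population-mean beta = 1.16
frame, truth = simulate_study(SimulationConfig(seed=42))
frame = frame[~frame["is_test"]]          # drop the designated test trial

model = PathChoiceModel(frame)
results = model.fit(chains=4, tune=2000, draws=10000, seed=1)
print(headline_numbers(results))
```

prints (numbers from this exact run):

```
{'beta_population_pooled': 1.14, 'beta_population_hyper': 1.14,
 'rho_mean': 0.25, 'shade_discount_factor': 0.88, 'percent_closer': 12,
 'beta_pooled_set_1': 1.14, 'tau_set_1': 0.183,
 'beta_pooled_set_2': 1.14, 'tau_set_2': 0.214}
```

Read: the fitted population distribution of β has mean 1.14 — walking a
sunny stretch feels ~14% longer than the same stretch in the shade, i.e.
a fully shaded path is perceived ~12% "closer" (discount factor 1/β ≈
0.88), close to the generating population mean of 1.16. The per-choice-set
temperatures recover the generating τ = 0.2.
The tree-shade intensity ρ is only weakly identified at this cohort size
(posterior mean 0.25 against a generating 0.5, with a wide interval) — 552
choices pin down β and τ much better than ρ, which is exactly why
`results.summary()` reports credible intervals and not just means.

Indifference arithmetic turns β into metres: at β = 1.16,
`sun_equivalent_distance(100, 1.16) == 86` (100 m of shade trades against
86 m of sun) and `mixed_exposure_sun_component(100, 50, 1.16) == 43`
(or against 50 m shade + 43 m sun).

A command-line pipeline wraps the same functionality:

```bash
pathshade simulate --seed 1 --out decisions.csv --scene-out scene.geojson
pathshade shade    --scene scene.geojson --events events.csv --out comp.csv
pathshade classify --decisions decisions.csv --rho 0.5 --out labels.csv
pathshade fit      --decisions decisions.csv --seed 1 --out posterior.nc
pathshade report   --posterior posterior.nc --decisions decisions.csv \
                   --out-dir report/ --paper-numbers
```

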