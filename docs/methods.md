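# Methods

## The occupancy-turnover model

Each habitat patch hosts a local population that follows a yearly
two-state Markov chain. For a given species, an occupied patch keeps its
population to the next breeding season with annual survival probability
S_i ("resistance") and an empty patch gains one with annual colonization
probability C_i ("resilience"). Both probabilities are modelled on the
logit scale as linear functions of patch covariates:

- **area** (ha, lognormal across real networks; entered untransformed),
- **circularity** 4π·area/perimeter² (1 for a circle; low values mean a
  high edge:area ratio),
- proportions of three vegetation-condition categories — **disturbed**,
  **undisturbed**, **mixed** — with the fourth (moderately disturbed)
  left out as the reference so the compositional covariates do not sum to
  a constant,
- **connectivity** S_i = Σ_{j≠i} p_j·exp(−α·d_ij)·A_j^b, the
  incidence-function score over occupied source patches, computed from
  year-1 occupancy. A_j is the source's carrying capacity: density × area
  when a per-species density column exists, otherwise area (the classical
  proxy). b scales emigration with abundance and defaults to 1.

Colonization models are fitted on the patches the species was absent from
in year 1 (response: present in year 2), survival models on the patches
it occupied (response: still present). Habitat covariates are taken from
the year-2 survey; connectivity from year-1 occupancy. Patch types a
species does not use (shoreline fringe, broad wetland — configurable
per-species flags) are excluded from its datasets, as are patches
unsurveyed in either year (logged, never imputed). A patch with no
perimeter has no circularity and is dropped from the model frame with a
warning rather than imputed.

## Dispersal-kernel estimation

α (per unit of the distance matrix; 1/α is the mean dispersal distance of
the exponential kernel) is estimated from the colonization dataset by a
deterministic profile likelihood: on a grid of α values (default 200
log-spaced points), the connectivity of every colonization-dataset patch
is recomputed and the Bernoulli log-likelihood of the observed outcomes
under a logistic model in S_i(α) is maximized over intercept and slope.
The α with the highest profiled likelihood is reported together with the
whole curve. Two diagnostics guard against over-interpretation: a
likelihood range below 2 log-units flags a flat (non-identifiable)
profile — the expected outcome when colonization carries no distance
signal, as the response-shuffled control in `analysis/02_estimate_alpha.py`
demonstrates — and a maximum at a grid endpoint raises a boundary
warning. A grid search was chosen over MCMC because the estimate is a
one-dimensional profile with no latent states; it is exactly reproducible
and needs no tuning. Distance units are recorded on the matrix and never
rescaled silently, because α is only meaningful per that unit.

## Model selection and averaging

Before selection, each vegetation proportion is screened for curvature:
a single-predictor model is compared with the same model plus the squared
proportion, and the squared term enters the global model only when plain
AIC strictly decreases (ties drop the term). Ranking of the all-subsets
candidate set then uses AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); the screening
step deliberately uses AIC, the ranking AICc. Subset enumeration enforces
marginality (a squared term never appears without its linear term) and is
guarded at 12 non-intercept terms.

The top set is every model within ΔAICc ≤ 2 of the best, boundary
inclusive, with Akaike weights w_m ∝ exp(−Δ_m/2) renormalized within the
set (ties broken by fewer parameters, then term order, for deterministic
output). Coefficients are full-model averaged: β̄ = Σ w_m·β_m with β_m = 0
where the term is absent, unconditional standard error
Σ w_m·√(var_m + (β_m − β̄)²), a normal 95 % CI on that SE, and relative
importance RI = Σ w_m over the models containing the term. Conditional
(natural) averaging is available as a function but is not the default,
since full averaging is the standard choice when prediction across the
whole network is the goal; the zero-substitution shrinkage it applies to
weakly supported terms is why the synthetic-recovery tests assert a
coverage floor of 85 % rather than nominal 95 %. How to compute CIs for
averaged coefficients is genuinely open in the literature; the
unconditional-SE normal interval implemented here is the most widely used
convention.

Logistic fits use IRLS (statsmodels GLM, binomial family, logit link,
deviance tolerance 1e-8). Quasi-complete separation — unavoidable when a
species shows only a handful of events — is detected by degenerate
responses or coefficients beyond ±15 on the logit scale and flagged with
a warning; estimates are still returned, with the inflated SEs that
separation produces, mirroring the plain-ML treatment such data usually
receive. Prediction applies the averaged linear predictor to every
suitable patch in the network (not only the fitting subset) through the
inverse logit.

## Steady-state persistence and classification

With constant S and C the chain's stationary occupancy has closed forms:
P = C/(1−S+C) without rescue, and P = C/(1−S+S·C) when a population that
goes extinct can be re-founded by colonists in the same season (extinction
followed by same-year colonization with probability (1−S)·C). Rescue
never lowers P, and can push it above one half even when S + C < 1;
without rescue P = 1/2 exactly on the line S + C = 1. The degenerate
corner S = 1, C = 0 has two absorbing classes; the functions return NaN
with a warning there instead of picking a limit. A seeded single-patch
simulation oracle (`markov_equilibrium_simulation`) validates both forms
and is re-run inside the acceptance script.

Patches are classified on (S, C) directly — the two axes are what a
manager can act on — with both P values always emitted alongside.
Thresholds default to 0.5 per axis and are configurable per species and
per axis; a value equal to the threshold counts as "high" (deterministic,
documented tie rule). Rescue mode defaults to on, since breeding
phenology in systems with year-round or rainy-season breeding makes
same-year re-establishment plausible; nothing downstream depends on the
choice because both P columns are always produced.

## Multi-species overlap

Per-species maps are harmonized before counting: predictions for
broad-wetland species are allocated down from each broad wetland to the
papyrus patches it contains (classification happens before allocation, so
categories are inherited intact); shoreline patches are forced to
"marginal" for species that never use them, on the overlap layer only;
and patch types outside a species' habitat that carry no prediction are
synthesized as marginal so all species cover one comparable universe
(papyrus + shoreline patches, plus any broad wetland that contains no
papyrus patch, which is kept as its own unit with a warning).
Harmonization is idempotent. Overlap output gives, per patch, the species
count in each category and in six derived layers: both-high, both-low,
high resistance (any resilience), high resistance & low resilience, high
resilience (any resistance), and low resistance & high resilience.

## Synthetic data: what it emulates, and what it does not

`synthetic_data` draws patch centres uniformly over a square extent
(default 10 km side), areas lognormal on ha (μ=0, σ=0.7 — median 1 ha
with a realistic right tail), circularity Beta(5, 2) realized through the
implied perimeter, vegetation proportions Dirichlet(2, 4, 3, 1.5)
(moderately disturbed dominant), and configurable shoreline/broad-wetland
fractions with containment links to the nearest broad wetland. Occupancy
then evolves by exactly the process the models estimate, with
connectivity recomputed from each year's occupancy.

Default generating coefficients (colonization logit −2.2 + 0.4·area +
0.5·S_i; survival logit 1.0 + 0.5·area − 3.0·mixed) were chosen so that a
1000-patch network yields event counts in the regime of a real two-year
survey of this kind — roughly 90 colonizations and 125 extinctions — and
so that the terms truly in the model are detectable at the strength such
surveys report for their leading predictors; the recovery tests
(sign agreement ≥ 95 %, CI coverage ≥ 85 % over 50 seeds) are run at
exactly these conditions. Distances are Euclidean between patch centres,
standing in for digitized nearest-edge distances; the generator does not
attempt lake-shore geometry, spatially correlated vegetation, observation
error (detection is assumed perfect, as near-certain detection was the
premise of the source surveys), or multi-species interactions. Passing
tests therefore show the estimators recover the generating process under
idealized spatial structure, not that any particular field system obeys
that process.

All randomness flows from one explicit seed through `numpy` SeedSequence
spawning (one substream for the network, one per species), so every
configuration reproduces byte-identically across platforms.

## Numerical and design choices

- Areas are stored in ha, distances in m; conversions are centralized
  (`HA_TO_M2`). Loaders refuse coordinates that fit in lat/long ranges
  rather than silently computing degenerate metre distances.
- Vegetation proportions within 1e-3 of summing to 1 are renormalized
  (hand-entered tables); larger deviations are errors naming the patch.
- Covariates enter unstandardized; the reported coefficients are on the
  raw scale.
- The ΔAICc ≤ 2 boundary is inclusive; AICc ties are broken by parameter
  count then term order.
- Semivariogram residuals default to response residuals (observed 0/1 −
  predicted probability), with deviance residuals behind a flag; default
  lags are 10 equal-width bins to the 60 % quantile of pairwise distances.
  Empty bins are reported as undefined (NaN), never zero.
- GeoJSON I/O uses shapely directly (area/perimeter/centroid derived from
  the polygon when not supplied as properties).

## Known limitations

- Two survey years give one transition per patch; S and C are estimated
  cross-sectionally from the network, not per patch over time, and the
  steady-state formulas extrapolate a single year-pair to the long run.
- Model-averaged CIs use the unconditional-SE normal approximation;
  bootstrap alternatives are not implemented.
- Species with very few events (3–10) yield separation-prone fits; the
  package warns and reports plain-ML estimates rather than switching to
  penalized likelihood by default.
- The α profile likelihood conditions on the observed year-1 occupancy
  pattern; it does not propagate uncertainty in the occupancy process
  itself.
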