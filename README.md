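# papyrusnet

Site-level **resistance** (survival of an occupied patch) and **resilience**
(colonization of an empty patch) for species living in fragmented habitat
networks, estimated from two-year presence/absence surveys.

The package is built for the kind of data a metapopulation field study
produces: a table of habitat patches (area, shape, vegetation condition,
projected coordinates, patch type) and a patch × species × year occupancy
table over two consecutive breeding seasons. From these it

1. computes incidence-function **connectivity** for every patch,
   `S_i = Σ_{j≠i} p_j · exp(−α·d_ij) · A_j^b`, with `p_j` the year-1
   occupancy of patch *j*, `d_ij` the nearest-edge distance, `A_j` the
   carrying capacity (density-weighted area where densities are available,
   raw area otherwise) and `α` the decay rate of the exponential dispersal
   kernel (`1/α` = mean dispersal distance); `α` can be estimated from the
   colonization events by a deterministic profile-likelihood grid search;
2. fits binomial-logit **turnover models**: colonization models on the
   patches a species was absent from in year 1, survival models on the
   patches it occupied, with patch area, circularity (`4π·area/perimeter²`),
   vegetation proportions (plus AIC-screened squared terms) and
   connectivity as predictors; all subsets of the global model are ranked
   by AICc, the set within ΔAICc ≤ 2 of the best model is full-model
   averaged (zero substitution, unconditional SEs) and each term's
   relative importance (summed Akaike weights) reported;
3. converts the predicted annual probabilities S and C into **steady-state
   persistence** of the per-patch two-state Markov chain,
   `P = C/(1−S+C)` without rescue and `P = C/(1−S+S·C)` when extinctions
   can be rescued by same-year colonists, classifies every patch into
   resistant-and-resilient / resistant-only / resilient-only / marginal
   quadrants, and
4. overlays the per-species classifications into **multi-species overlap
   maps** (with broad-wetland predictions allocated down to the papyrus
   patches they contain, and shoreline patches marked marginal for species
   that never use them).

A synthetic-data module generates patch networks and occupancy dynamics
with known ground truth, so every stage is testable without field data.

## Worked example

The numbered scripts under `analysis/` run a complete five-species study
on a seeded synthetic survey (500 patches, two years). `python
analysis/01_simulate_study.py` prints the turnover accounting:

```
                species  surveyed  colonized  survived  extinct  vacant
  warbler_low_dispersal       450         44       182       51     173
   canary_mid_dispersal       450         39       164       53     194
cisticola_mid_dispersal       375         49       155       29     142
       warbler_interior       325         27       119       23     156
 warbler_high_dispersal       375         28       144       47     156
```

Each row partitions the surveyed suitable patches by their year-1 → year-2
transition; `colonized + vacant` is the colonization-model sample,
`survived + extinct` the survival-model sample. `python
analysis/02_estimate_alpha.py` recovers the dispersal kernel from the
colonization events:

```
true alpha 0.1/m -> estimate 0.1123/m (mean dispersal 8.9 m); flat=False, boundary=False
shuffled-response control: flat diagnostic fired = True
```

`python analysis/03_fit_and_classify.py` fits, averages, predicts and
classifies every patch, then overlays the five species:

```
warbler_low_dispersal: significant colonization terms ['intercept', 'area']; 1% of patches resistant and resilient
...
overlap: 0 patches are high-resistance & high-resilience for all 5 species; max per-patch overlap 4
```

`python analysis/04_steady_state_surfaces.py` maps both persistence
surfaces and verifies them against 10⁵-step Markov-chain simulations
(closed form 0.6000 vs simulated 0.5992 at S=0.8, C=0.3, and so on).

The same stages are available as a CLI (`papyrusnet simulate|fit-alpha|
run-all`) and as a library (`papyrusnet.run_pipeline` with a validated
YAML config; every run directory gets a manifest with the config hash and
seed, and identical configs reproduce identical outputs).

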