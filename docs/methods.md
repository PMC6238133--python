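# Methods

## Model

The package estimates age-specific natural mortality jointly from many
small, heterogeneous literature datasets.  Mortality is parameterised
through the cumulative hazard of a reduced additive Weibull (RAW)
distribution, H(t) = (at)^b + (at)^(1/b) + ct, so S(t) = exp(−H(t)) and
λ(t) = H′(t) = ab(at)^(b−1) + (a/b)(at)^(1/b−1) + c.  The three parameters
have interpretable roles: `a` (per year) sets the overall time scale of
both Weibull terms, `b` (> 1) controls how sharply juvenile mortality
decays and senescent mortality rises, and `c` (per year) is an
age-independent hazard floor.  The hazard diverges at t = 0 (the exponent
1/b − 1 is negative), which is mathematically harmless — H is finite — but
means hazard evaluation at exactly 0 is treated as a domain error and
curves report NaN there.

Age conventions: t = 0 is birth, annual survival φ_t = S(t+1)/S(t) spans
[t, t+1), "yearling survival" is S(1).

Between-dataset structure is proportional hazards, λ_d = ψ_d λ, rather
than hierarchical structure on (a, b, c) directly: multiplicative hazard
offsets keep every dataset's curve the same shape, which is restrictive
but vastly more stable to fit, and make S_d = S^ψ_d a one-liner.  log ψ_d
is a sum of centred Gaussian effects over the nested levels subfamily ⊃
species ⊃ study ⊃ dataset; the study and dataset levels absorb phenotypic
plasticity and methodological artifacts rather than taxonomy.  Each active
level k has precision τ_k with a Gamma(α_k, β_k) hyperprior; defaults
α = 1.0, β = 0.1 (mean 10, i.e. effect SD ≈ 0.3, weakly informative toward
pooling), initial τ = 0.1.  The 16 candidate models are all subsets of the
four levels; they are compared by DIC.

## Observation models

* **Age-specific estimates.**  logit(φ̃_t,d) ~ Normal(logit φ_t,d, 1/τ)
  with φ_t,d = (1 − h_d)·S_d(t+1)/S_d(t).  Harvest is a pulse: a fraction
  h_d of each year's survivors is removed, so reported total survival is
  natural annual survival times (1 − h_d).  h_d is age- and time-invariant
  with prior Uniform(0, 2·h̃_d), where the rough rate h̃_d is a user input
  (use something tiny, e.g. 0.001, for unharvested populations; h̃_d must
  be ≤ 0.5 so the support stays inside [0, 1]).
* **Precision of reported estimates.**  With a reported SE, the delta
  method gives τ = φ̃²(1 − φ̃)²/SE².  With a confidence interval,
  SE = (hi − lo)/(2 z_level) first (intervals are assumed symmetric on the
  probability scale, as typically reported).  With only a sample size n,
  the binomial SE = sqrt(φ̃(1 − φ̃)/n).  With nothing, a conservative
  logit-scale SD of 1.0 (config `default_logit_sd`); this default is this
  package's choice, deliberately vague so uninformative estimates cannot
  dominate.
* **Age-range estimates** are matched to the abundance-weighted average of
  the per-age φ_t,d over [t1, t2]: the weight of age t is the expected
  fraction of a cohort still alive at t relative to the t1 class.  Weights
  use harvest-adjusted survival by default (config
  `range_weights_use_harvest`) because the standing age structure of a
  harvested population reflects total mortality.  Open-ended ranges
  ("5+") are closed at `max_age` (default 60 y, where S < 1e-6 for any
  plausible parameters of a phocid-sized mammal).
* **Catch-at-age counts** are multinomial over ages with cell
  probabilities from the same cohort projection, assuming equal harvest
  rates across ages and years; counts start at age 1 by default (config
  `first_catch_age`) since newborns do not appear in harvests.

Reported estimates of exactly 0 or 1 are truncated to [1e-6, 1 − 1e-6]
with a warning so their logit stays finite.

## Priors on the master parameters

The hazard parameters get weakly informative Normal priors on the
unconstrained scale used by the sampler: log a ~ N(log 0.1, 1.5²),
log(b − 1) ~ N(0, 1.5²), log c ~ N(log 0.01, 1.5²).  Two standard
deviations cover hazards from rodent-like to whale-like U-shapes; all are
config-overridable.  Parameter constraints (a > 0, b > 1, c ≥ 0) are
enforced by the transforms; constructing out-of-domain `RAWParams`
directly is an error, never a silent clamp.

## Sampling

The sampler is adaptive random-walk Metropolis-within-Gibbs, all seeded
and bit-reproducible:

* blocks: one global block over all non-precision parameters plus refining
  blocks (master parameters, each level's effects, harvest rates).  Each
  block proposes jointly from a Gaussian whose scalar step follows a
  Robbins–Monro recursion toward 25–44% acceptance and whose shape tracks
  the running empirical covariance (diminishing adaptation);
* the level precisions τ_k are updated by their exact conjugate Gibbs
  draw Gamma(α + n_k/2, β + Σε²/2) in the centred parameterisation.  A
  non-centred parameterisation (ε = z/√τ, useful with very few groups) is
  available via `non_centered=True`, in which case τ_k gets its own
  adaptive block;
* initial states are prior medians jittered per chain, effects near 0,
  τ_k at its configured initial value 0.1; a non-finite start triggers
  bounded re-initialisation;
* defaults are 3 chains × 15,000 iterations, 5,000 burn-in, thinning 10
  (3,000 retained draws).  Burn-in/thinning are applied per chain;
  diagnostics use unpooled chains.

Convergence is summarised by a split-chain Gelman–Rubin statistic (each
chain halved, classic between/within variance formula); < 1.1 on every
parameter is the working threshold.  DIC uses the Spiegelhalter effective
parameter count pD = mean(D) − D(θ̄) with θ̄ the posterior mean on the
unconstrained scale; `pd_method="variance"` switches to var(D)/2, the
JAGS-style convention, which is often materially different — DIC
*rankings* are stable across the two in our experiments, absolute pD
values are not.  If θ̄ falls outside the support the variance form is used
with a warning.

## Prediction and bias correction

Because log ψ is Gaussian, exponentiating only the retained effects
understates a real-scale mean: reporting at a level above the deepest
fitted one multiplies in exp(0.5 Σ 1/τ_k) over the omitted deeper levels,
within each posterior draw.  A natural-mortality prior for a data-free
population of a fitted species simulates a fresh effect for every active
level below species (per draw) — the default, fast route — or refits with
an appended all-missing dataset, which is the generative mechanism itself;
the two agree on simulated data and the agreement is a test.  Curve
evaluation defaults to ages 0–40 by 0.25.

## Synthetic data

The generator inverts the model: draw ε per group from the specified
level SDs, form ψ_d, compute true harvest-adjusted survivals, add
logit-scale Normal noise, and draw multinomial catches with
Poisson-distributed cohort totals.  Reported SEs are the delta-method
image of the generating logit SD, so the reader recovers the generating
precision exactly.  The standard study design (`simulate_study`) uses 8
datasets over 4 species and 2 subfamilies, species- and dataset-level SDs
of 0.2, truth a = 0.054, b = 2.6, c = 0.006 (a phocid-scale U-shape),
half the datasets harvested at a true rate 0.08 with rough input 0.1 and
half essentially unharvested (0.0005 true, 0.001 rough); each dataset
carries age-specific estimates at ages 0–9 with logit SD 0.15, two range
estimates (1–4 and 5+), and one catch cohort of Poisson(200) animals over
20 ages.  What the generator does *not* emulate: permanent emigration
(apparent vs true survival), age- or time-varying harvest, reporting or
selectivity biases in catch data, non-RAW hazard shapes, and correlation
of observation errors within a study.  Passing recovery tests therefore
shows internal consistency of model + sampler, not robustness to those
real-data violations.

## Problem sizes in the shipped checks

The test suite and acceptance script run the recovery and model-selection
experiments at the standard 8-dataset design with 20 (tests) or 10
(script) replicates; replicate fits use the full 3 × 15,000 sampler
settings for recovery/coverage and shortened chains (2 × 4,000) for the
DIC comparisons, where the between-model separation is orders of
magnitude larger than chain noise.  These sizes are the package's standard
desk-scale experiment; the full 39-dataset, 16-model analysis is run
through the same code path via the data deposit described in the README.

## Known limitations

* A single ψ_d per dataset forces identical hazard shape everywhere;
  datasets with genuinely different senescence patterns will show
  lack-of-fit (visible as large |ε_dataset|), and species with no
  documented senescence can inherit an artifactual late-life hazard rise
  from the ensemble.
* DIC with missing-data structures is known to count parameters
  erratically; pD should be sanity-checked against the parameter count.
* The pulse-harvest adjustment ignores within-year timing of harvest
  relative to natural mortality.
* Catch-at-age likelihoods treat sampling as age-uniform; real harvests
  are selective.
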