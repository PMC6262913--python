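# Methods

This note documents the models, algorithms, and design choices behind
`choicersf`, in the spirit of a statistical package's model documentation.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The discrete-choice RSF

A choice set pairs one used habitat unit with `m` available units (default
`m = 5`). The probability of the observed choice is the conditional logit
(softmax of linear utilities); the log-likelihood over a track is the sum of
log chosen-probabilities. Key modelling facts:

* **No intercept.** Any design column constant within a set cancels from
  the probability ratio, so the design carries no intercept and the
  categorical habitat layer is reference-coded (K−1 indicators; the first
  label is the default reference). A corollary tested explicitly: shifting a
  covariate by a constant across all alternatives of a set leaves the
  probabilities unchanged.
* **Numerics.** Every probability/likelihood evaluation subtracts the
  per-set maximum utility before exponentiation, so arbitrarily large |β|
  cannot overflow. At extreme utilities non-maximal probabilities can
  underflow to exactly 0 in double precision; this is harmless for the
  likelihood of the chosen alternative, which is computed in log space.
* **Concavity.** The conditional-logit log-likelihood is concave in β; the
  analytic gradient and Hessian are implemented and used by the MAP
  optimizer and verified against finite differences in the tests.

## Availability

The availability radius is `c (a + 2b)`: `a` and `b` are the mean and
sample SD of the hourly movement rate over consecutive fixes, `c` the
nominal fix interval (5 h, the collar schedule; an observed-median-gap mode
exists). Rates divide step length by the *actual* elapsed time, so missed
fixes do not inflate speeds, and steps whose gap exceeds twice the nominal
interval are excluded from `a`, `b` — long gaps say little about travel
rate, and including them inflates `b` and hence the buffer. Available
points are rejection-sampled uniformly on the buffer disc intersected with
the grid extent; a fix whose buffer lies essentially outside the mapped
area is dropped with a logged count. Available points may fall in the used
cell (random sampling within the buffer, no exclusion). Alternatives are
treated as points carrying their 30 m cell's covariates, with row-major,
0-based cell indexing from the lower-left origin corner and half-open
point-in-cell intervals.

## Collinearity screen

Pearson correlations are computed over the continuous design columns pooled
across all alternatives. While any pairwise |r| exceeds the threshold
(0.6), the worst-offending pair is located and the member with the larger
mean absolute correlation to all other retained columns is dropped (lexical
tie-break); zero-variance columns are dropped first with a warning.
Categorical indicators are exempt. This is a deterministic, reproducible
analogue of the usual judgement call about which of two redundant variables
to keep, and on three-variable problems it provably matches the
minimal-removal enumeration oracle used in the tests.

## Posterior sampling

The per-individual posterior is the conditional-logit likelihood times
independent Normal(0, `prior_scale`) priors on each coefficient
(`prior_scale = 10`, matching the population-level hyperprior scale; the
individual-level prior is otherwise unconstrained by convention, so it is
configurable). Sampling uses four chains of 1,000 draws with a 200-draw
burn-in — 3,200 retained draws.

The sampler is a seeded Metropolis scheme with two mixed kernels:

* an **independence kernel**: a multivariate t (df 7) centered at the
  posterior mode with 1.2× the Laplace covariance. The posterior is
  smooth, concave-log-density, and nearly Gaussian at realistic numbers of
  choice sets, so this proposal is accepted most of the time and yields
  nearly independent draws irrespective of dimension;
* an **adaptive random-walk kernel** (running-covariance proposal scaled by
  2.38²/d with an acceptance-rate correction) that guarantees local
  exploration when the Laplace approximation is poor (e.g. tiny data sets).

Chains start at the mode plus overdispersed jitter scaled by the Laplace
standard deviations. Adaptation happens during burn-in only; retained draws
come from a frozen kernel, so the post-burn-in chain is a valid
time-homogeneous Markov chain. Any seeded sampler passing the convergence
thresholds would satisfy the same contract; a gradient-based backend could
be slotted behind the same interface.

### Diagnostics

R̂ is the split-chain potential scale reduction factor (plain, not
rank-normalized); n̂_eff combines chain-averaged FFT autocovariances with
the split-chain variance estimate, truncating the autocorrelation sum at
the first non-positive Geyer pair sum and forcing the pair sums
non-increasing. Thresholds follow the usual applied practice: R̂ < 1.1 and
n̂_eff > 100 per parameter; violations warn but do not abort (the result
carries the numbers). A chain with identical split halves yields
R̂ = √((n−1)/n), marginally below 1 — the estimator's floor, not an error.
Both implementations are cross-checked against arviz in the test suite.

### Posterior predictive check

The discrepancy is the chi-square statistic T(y, θ) = Σ_i (y_i − p_i)²/p_i
with `i` ranging over every alternative of every set (the multinomial-cell
reading; a per-choice-set variant, indexing only the chosen alternative of
each set, is available behind the `per_set` flag — the conventional
notation is ambiguous between the two, and the per-alternative form is the
default because it uses every cell of the multinomial). For each of
`n_reps` (default 500) posterior draws, replicate choices y* are simulated
from the draw's own probabilities; p_B = Pr(T(y*, θ) ≥ T(y, θ)). Values
near 0 or 1 diagnose misfit; calibration on well-specified synthetic fits
is part of the acceptance suite.

## Model selection

Candidates are all 2^V − 1 non-empty subsets of the screened
variable-level terms, with habitat entering or leaving as a single block
(per-indicator subsets are not meaningful). An enumeration cap (default 16
variables) guards against accidental explosions; an explicit candidate list
can override the enumeration. WAIC is computed from the pointwise posterior
log-likelihood matrix: lppd via a stable log-sum-exp over draws, p_WAIC as
the per-set sample variance over draws, WAIC = −2(lppd − p_WAIC). Ranking
is ascending WAIC with ties broken by fewer parameters then lexical
variable order. Candidate fits default to a reduced budget (2 chains × 600
draws, 150 burn-in) with the full budget reserved for the winner — WAIC
*ordering* is robust to this level of Monte-Carlo error, which the
selection acceptance test exercises directly. Inclusion rates take the top
⌈0.05 · n_models⌉ models.

## Hierarchical population model

Random slopes: β_jk ~ Normal(μ_k, σ_k²) independently per covariate k (no
cross-covariate correlation), hyperpriors μ_k ~ Normal(0, 10),
σ_k ~ Uniform(0, 10). The sampler is Metropolis-within-Gibbs on the
non-centered parameterization β_jk = μ_k + σ_k z_jk (funnel avoidance at
small σ), with per-sweep blocks:

1. all individuals' z_j vectors in parallel (the likelihood factorizes
   over individuals, so acceptances are independent);
2. μ and σ random-walk blocks;
3. two **ridge moves** that hold every β_jk fixed: a shift
   (μ, z) → (μ + δ, z − δ/σ) and a rescale (σ, z) → (σe^δ, ze^{−δ})
   with its Jacobian. The likelihood cancels exactly in both, so they
   travel along the strong μ/z and σ/z posterior ridges at negligible
   cost — this is what makes the hyperparameters mix at desk scale where
   each β_j is tightly determined by its own data.

Chains initialize from per-individual MLEs (μ at their mean, σ at their
spread, z at the standardized residuals) with overdispersed jitter; block
step sizes adapt toward 30% acceptance during burn-in only. A prior-only
mode drops the likelihood so the machinery's reproduction of the
hyperpriors can be verified by Kolmogorov–Smirnov tests. The hierarchical
summary reports, per covariate: posterior mean and 95% CI of μ_k, the σ_k
point estimate, and draw-wise 95% CIs of μ_k ± σ_k (the "box ends" of a
random-effects forest plot). The "random effect excludes zero" flag uses
the μ ± σ derived intervals (both on the same side of zero); the shrinkage
report separately flags independent estimates outside the μ ± 2σ band,
since the appropriate derived quantity is a judgement call and both are
informative.

## Maps

Relative use is exp(β·x) per cell (posterior-mean β), min–max rescaled to
[0, 1]; the normalization is a display convention only — map comparisons
use Spearman ρ (average ranks for ties), which is invariant to any
monotone rescaling, a property asserted in the tests. A constant surface
(e.g. β = 0) has no rank structure and is returned as all zeros with a
warning; its correlation with anything is undefined (NaN). A draw-wise
cell-sd uncertainty map is available. The ρ distribution table uses
closed-lower-bound tenth bins from 0.9 down to 0, plus one bin for
negative ρ.

## Synthetic data

The generator exists so every stage can be tested against known truth.

* **Landscapes** are Gaussian-kernel-smoothed white-noise fields
  (wrap-around boundaries), standardized per layer, then mixed through the
  Cholesky factor of a target cross-correlation matrix — simple,
  dependency-light, and controllable, at the cost of exactly Gaussian
  marginals and a single isotropic autocorrelation range. Habitat
  rank-slices one extra latent field into near-exactly equal classes
  (default 8, labelled after a grassland/woodland mosaic). Circular
  covariates (aspect-like) are generated as plain continuous fields; no
  circular structure is attempted.
* **Tracks** are the generative twin of the fitted model: per 5 h step,
  `m_sim` candidate destinations uniform in a disc of radius `R` (default
  1,000 m, a plausible elk-scale reach per fix interval; out-of-extent
  candidates rejected), softmax selection by the true utilities. Sampled
  candidates rather than full-disc cell enumeration keep runtime at desk
  scale and mirror the used/available logic. Coordinates are planar meters
  (projected CRS assumed); there is no geographic lat/long support because
  the movement-rate arithmetic presumes planar distances.
* **Direct choice data** (`simulate_choice_data`) skips the landscape:
  standard-normal covariates per alternative and softmax choices. This is
  the cleanest harness for recovery/calibration experiments.
* **Heterogeneous individuals** draw β_j ~ Normal(μ, σ²) per covariate.

What the generator does *not* emulate: memory, home-range attraction,
herding, terrain-derived covariates, irregular fix schedules, habitat-
dependent movement rates. Passing tests therefore demonstrate the
*statistical machinery* is correct under the model's own assumptions, not
that the model captures real elk behaviour.

## Problem sizes and reproducibility

Validation experiments are sized for a single desktop core: the canonical
individual fit uses 1,000 choice sets with 6 alternatives and 3 covariates;
recovery/calibration checks run 20 replicates; all-subsets selection runs
10 replicates of 31 candidates; hierarchical recovery runs 5 replicates of
20 individuals × 400 sets. These sizes give each check enough resolution
for its stated bound while keeping the whole suite at desk scale (a
full-size field study — on the order of 10^5 pooled choice sets and ~17
parameters — is accepted by the same code paths but flagged as
long-running). All randomness flows through per-call seeded generators;
batch sub-seeds derive deterministically from the master seed and the
individual's ID (CRC32-based, below 2^31), so batch results are independent
of processing order and any bundle can be reproduced from its manifest.

## Known limitations

* The independence-kernel sampler leans on the Laplace approximation;
  posteriors from very small or separable data sets fall back to the
  random-walk kernel and may need longer chains (diagnostics will say so).
* WAIC at the reduced candidate budget carries Monte-Carlo noise of a few
  units; near-ties between nested models can swap ranks between seeds.
* σ_k is informed by the *realized* spread of the sampled individuals; with
  few animals its posterior tracks that realized spread, not the
  superpopulation value.
* Step-selection variants (movement covariates, turn angles), home-range
  availability polygons, correlated random effects, and RSPF estimation are
  out of scope.
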