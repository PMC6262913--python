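# choicersf

Individual-level Bayesian discrete-choice resource selection functions
(RSFs) for wildlife telemetry — with a synthetic-data stack (landscapes,
heterogeneous individuals, GPS-like tracks) so the whole pipeline can be
validated end to end against known truth.

## The problem

Habitat-selection studies usually pool GPS fixes from many collared animals
and fit one population-level RSF. Pooling can mask real individuality: two
animals in the same landscape may select the same covariate in opposite
directions, and the pooled map then describes nobody. This package
implements the per-animal alternative and the machinery for comparing it
with the pooled approach:

1. **Choice sets.** Each GPS fix is a *used* habitat unit. Availability is
   delimited per fix by the radius-of-available-habitat rule
   `r = c (a + 2b)`, where `a` and `b` are the mean and standard deviation
   of the animal's hourly movement rate and `c` the hours between fixes;
   five random points in that buffer are the *available* units.
2. **Discrete-choice RSF.** The probability that the animal chose unit `l`
   from choice set `i` is the conditional logit

   P_il = exp(β·x_il) / Σ_c exp(β·x_ic),

   with utility β·x over the unit's covariates (continuous layers plus a
   reference-coded categorical habitat class; no intercept, since within-set
   constants cancel).
3. **Bayesian fitting.** Posteriors are sampled with four chains of 1,000
   draws (200 burn-in) under Normal(0, 10) priors; convergence requires
   split R̂ < 1.1 and n̂_eff > 100 for every parameter. Goodness of fit uses
   a chi-square posterior predictive check whose Bayesian p-value `p_B`
   flags misfit when near 0 or 1.
4. **Model selection.** After screening covariates to pairwise |r| ≤ 0.6,
   all non-empty subsets of the remaining terms (habitat as one block) are
   ranked by WAIC = −2(lppd − p_WAIC); inclusion rates summarise the top 5%
   of models.
5. **Population model.** A hierarchical random-slopes model pools
   individuals: β_jk ~ Normal(μ_k, σ_k²) with hyperpriors
   μ_k ~ Normal(0, 10), σ_k ~ Uniform(0, 10).
6. **Maps.** Predicted relative-use surfaces min–max rescale exp(β·x) per
   cell; individual and population maps are compared by Spearman ρ and
   binned into the conventional reporting table.

## Worked example

```python
from choicersf import (McmcConfig, fit_individual,
                       posterior_predictive_check, simulate_choice_data)

data = simulate_choice_data([1.0, -0.5, 0.25], n_sets=1000,
                            n_alternatives=6, seed=11)
fit = fit_individual(data, McmcConfig(seed=12))
print(fit.summary().round(3))
print(posterior_predictive_check(fit, data, seed=13))
```

prints

```
parameter   mean    sd  ci_lo  ci_hi  rhat     neff
       x1  1.001 0.045  0.918  1.092 1.001 1618.551
       x2 -0.534 0.041 -0.617 -0.454 1.001 1585.339
       x3  0.294 0.040  0.213  0.371 1.004 1438.736
0.648
```

The posterior means recover the generating coefficients (1.0, −0.5, 0.25)
within their credible intervals, both convergence diagnostics are well
inside their thresholds, and the Bayesian p-value 0.648 shows no lack of
fit. The `examples/` directory holds one short script per capability, from
landscape simulation (`01`) through the full batch pipeline (`06`); a thin
CLI mirrors the pipeline (`choicersf run-all --tracks tracks.csv --grids
grids/ --out out/ --seed 1`).

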