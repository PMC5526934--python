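# caribou-pva

Demographic viability analysis for boreal caribou (*Rangifer tarandus
caribou*), a threatened late-seral ungulate whose populations decline as
boreal landscapes are burned, logged and roaded. The package is for
quantitative ecologists and wildlife managers who need to turn raw
monitoring data — collar telemetry and late-winter aerial surveys — into an
answer to the management question: *how much landscape disturbance can this
population withstand, given the productivity of its forest?*

## The model

Two vital rates are estimated per population and biological year
(1 April – 31 March) and modelled on the logit scale against the proportion
of total disturbance *D* and the proportion of potentially productive
forest stands *P*, with a random intercept per population and
precision weights:

- **Adult-female survival** `S_f` — staggered-entry Kaplan–Meier estimates
  (animals enter the risk pool at collaring, leave at death or censoring;
  population-years with fewer than 6 monitored females are dropped),
  modelled as `logit S_f = β₀ + β_D·D + β_P·P + u_pop`, weighted by the
  number of monitored females.
- **Recruitment** `R` (calves per adult female) — survey counts with
  unclassified adults apportioned by the observed sex ratio (or 65% females
  when ≥10% of adults are unsexed; surveys under 50 individuals are
  dropped), modelled as `logit R = β₀ + β_D·D_lag + β_{P²}·P²`, weighted by
  the corrected female count, with the *previous* year's disturbance.

The female-segment growth rate is

```
λ_f(D, P) = S_f(D, P) / [1 − R_f(D, P)],   R_f = (R/2) / (1 + R/2)
```

(even birth sex ratio). Since both disturbance coefficients are negative,
λ_f falls with D, and the **withstandable disturbance** D\*(P) solves
λ_f = 1. Uncertainty is propagated by simulating coefficient vectors from
each model's sampling distribution: the 95%-confidence limit is the largest
D at which λ_f ≥ 1 in at least 95% of draws. A succession module
(least-squares height/cover models, penalized-spline deciduous model)
quantifies why productivity helps: productive stands return to safe
closed-canopy conifer forest faster.

A seeded synthetic-data generator emulates all four inputs (collars,
surveys, range tables, inventory pixels) with the published coefficient
estimates as truth, so the whole pipeline is testable without any data
download.

## Worked example

```python
from caribou_pva.reference import published_recruitment_model, published_survival_model
from caribou_pva import predict_rate, mean_threshold, confident_threshold

s, r = published_survival_model(), published_recruitment_model()
print(predict_rate(r, 0.35, 0.21))   # 0.1405  calves/female, low-productivity range
print(predict_rate(r, 0.35, 0.85))   # 0.4560  calves/female, high-productivity range
print(mean_threshold(s, r, 0.85).d_star)                      # 0.579
print(confident_threshold(s, r, 0.85, n_sim=10000, seed=42))  # 0.225
```

At 35% disturbance, a population in a low-productivity range recruits 0.14
calves per female against 0.46 in a high-productivity range; the
point-estimate withstandable disturbance at P = 0.85 is ~58%, but to be 95%
confident of λ_f ≥ 1 disturbance must stay below ~22% (with only published
standard errors, no covariances, the confidence limit is conservative).
The `examples/` scripts walk through each capability — prediction,
Kaplan–Meier estimation, model fitting and recovery, thresholds,
succession, and the one-call pipeline — and print the numbers above.

There is also a thin CLI:

```
caribou-pva simulate --seed 1 --out data/
caribou-pva all --config pipeline.yaml --seed 1 --out results/
```

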