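# dlqivalue

Time trade-off (TTO) utility value sets for the Dermatology Life Quality
Index (DLQI).

The DLQI is the most widely used skin-specific quality-of-life questionnaire:
ten items scored 0–3, total score 0–30, and in many countries the total score
gates access to costly dermatological treatments. For cost-effectiveness
analysis, however, health states must be valued on the dead = 0 / full
health = 1 utility scale. `dlqivalue` implements the full pipeline for
estimating a societal DLQI value set from 10-year TTO valuations of
hypothetical health states described by DLQI severity profiles:

* **Study design** — orthogonal 64-state cores (exact level balance, zero
  pairwise item correlation, built from GF(4) orthogonal arrays), catalogue
  assembly, and randomized 5-state blocks that always contain the
  all-level-3 "worst possible" state.
* **Screening** — the respondent-exclusion cascade: non-traders (y = 1
  everywhere), identical responses, response-time and consistency rules,
  and the two-value uninformativeness rule, with a full audit trail.
* **Models** — seven random-intercept regression families linking
  thermometer-coded severity dummies x to utilities y = 1 − t/10: linear,
  two-sided censored (Tobit), equidistant ordered probit, beta regression
  (probit link, constant precision), and three two-part "scalable" variants
  built on the decomposition y = 1 − λz, z = α + x′β + u + v, where λ is an
  individual's effective scale range proxied by 1 − y(worst state). The
  random intercept is integrated out by adaptive Gauss–Hermite quadrature;
  all families report coefficients in comparable utility units.
* **Selection** — sign-constrained backward elimination followed by
  leave-one-block-out cross-validation across all seven families: the final
  model keeps only dummies whose coefficients are ≤ 0 in every fold of every
  family.
* **Value sets** — coefficient averaging (censored + scalable censored),
  cumulative partial effects per item × level, and the non-trader adjustment
  ŷ_a = w·1 + (1 − w)·ŷ; prediction for arbitrary states and exhaustive
  4^10 enumeration summaries.
* **Synthetic cohorts** — a generator for survey data with known ground
  truth (trader/non-trader/careless mixture, response times), so every stage
  is testable end-to-end.

## Worked example

Score DLQI states with the published reference value set (stored final-model
coefficients; no fitting needed):

```bash
$ dlqivalue predict 0000000000 3333333333 0030000100
0000000000  0.873
3333333333  0.576
0030000100  0.852
```

The all-zero profile maps to the societal intercept 0.873 (below 1 because a
fraction w = 317/2001 of the reference population would not trade any
lifetime, and the trader intercept is 0.849); the worst possible state maps
to 0.576; a profile with "a lot" on daily activities (Q3 = 3) and "a little"
on work/school (Q7 = 1) loses 0.021 utility.

Run the full pipeline on a simulated cohort (design → simulate → screen →
select → fit → value set), writing all artifacts plus a hashed manifest:

```bash
$ dlqivalue run-all --n 2001 --seed 1 --out-dir out --quick
{
 "accounting": {"initial_full_sample": 2001, "non_traders": 337,
                "excluded_identical": 325,
                "excluded_time_or_inconsistent": 548,
                "excluded_uninformative": 281, "final_traders": 510, ...},
 "w": 0.168...,
 "value_set_adjusted_intercept": 0.911...,
 "score10": {..., "iqr": 0.028..., "p95_minus_p5": 0.069...},
 ...
}
```

(`--quick` skips the cross-validated stage-2 selection; the screening
accounting, the non-trader weight w and the simulated value set then come
from the stage-1 sign-constrained model on this synthetic cohort.)

or from Python:

```python
import dlqivalue as dv

cat = dv.build_catalogue(dv.generate_orthogonal_core(64, rng_seed=1))
blocks = dv.assign_blocks(cat, n_blocks=18, rng_seed=2)
cohort = dv.simulate_cohort(cat, blocks, 2001, dv.SimulationParams(rng_seed=3))
outcome, traders = dv.screen_sample(cohort)

model = dv.TTORandomIntercept.from_dataframe(
    traders, dv.DummyDesign.full(), family="censored")
results = model.fit()
print(results.summary())
```

`results` carries the estimates, standard errors, variance components,
population-averaged predictions and fit indices; `as_fit_result()` converts
any family to utility-scale incremental coefficients for value-set
construction.

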