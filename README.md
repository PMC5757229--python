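# etpymodel

A Markov cohort cost-effectiveness model of adding a PCSK9 inhibitor
(evolocumab) to high-intensity statins in adults with heterozygous familial
hypercholesterolaemia (HeFH), written for health economists and HTA analysts
who want the full pipeline — baseline-risk construction, LDL-C-driven
treatment effects, state-transition dynamics, costing, and deterministic and
probabilistic sensitivity analysis — as tested, scriptable Python rather than
a spreadsheet.

## The model in brief

**Outcome measure.** The model's health benefit is the *effectively treated
patient-year* (ETPY): a year of survival weighted by the probability that the
patient attains the guideline lipid target of a ≥ 50 % LDL-C reduction,

```
ETPY = Σ_t  d(t) · p_eff(arm) · PY(t)
```

where `PY(t)` is half-cycle-corrected alive person-time in annual cycle `t`,
`d(t) = 1/(1+r)^(t−1)` the discount factor (r = 5 %/year), and `p_eff` the
arm's attainment proportion (79.25 % with evolocumab added, 1.96 % on statins
alone). The cost-effectiveness statistic is the incremental cost per
incremental ETPY (ICER, in BGN).

**Disease model.** A cohort enters a Markov state space of 11 base health
states (no CVD, established CVD, acute and post MI/ischaemic-stroke/heart-
failure states, CHD death, IS death, non-CVD death) plus composite chronic
states that remember multiple prior events; composites transition at the
highest member risk and are costed at the highest member cost. Baseline
event rates come from a 10-year primary-prevention risk score and a 20-month
secondary-prevention risk score (with an Eastern-Europe/Middle-East region
term), age-frozen at baseline, multiplied by a pooled FH rate ratio of 7.1
and calibrated to a 55 % 10-year risk of a first event.

**Treatment effect.** The relative LDL-C reduction (61.31 %) at baseline
LDL-C 155.46 mg/dL gives ΔLDL-C = 2.4648 mmol/L, applied through per-event
rate ratios per 1 mmol/L: the post-treatment event rate is

```
rate_treated = rate_baseline × RR_event ^ ΔLDL-C(mmol/L)
```

with RR = 0.71 (MI), 0.69 (IS), 0.80 (CHD death), 0.66 (revascularisation),
1.00 (IS death, fixed) and no effect on heart failure.

Risk-equation coefficients, national life tables, the fitted event-type
distribution and drug prices are not published at usable precision anywhere,
so the package generates labelled synthetic stand-ins with realistic
magnitudes; every one of them is an ordinary config input (YAML/CSV/JSON)
that can be replaced by real tables without code changes.

## Worked example

```bash
etpymodel run --out results/
```

prints (packaged synthetic base case):

```
                                 row  treatment   control  increment
                           Total LYs      12.43     10.87       1.56
                         Total ETPYs       9.85      0.21       9.64
                          Events: MI       0.90      1.77      -0.88
               Events: Any CVD event       2.53      3.67      -1.14
             Costs (BGN): Medication 133,972.10  1,391.67 132,580.42
             Costs (BGN): Total cost 148,410.39 22,039.68 126,370.71
              ICER (BGN/ETPY gained)                        13,112.00

ICER: BGN 13,112 per ETPY gained (icer)
```

Read: over a lifetime, the treated cohort gains 1.56 discounted life-years
and 9.64 ETPYs (most of the ETPY gain comes from the attainment proportion,
not survival), avoids 1.14 CVD events per patient, and incurs BGN 126,371 of
extra cost — almost entirely drug acquisition — for an ICER of about
BGN 13,100 per effectively treated patient-year gained.

Sensitivity analyses:

```bash
etpymodel sens --mode dsa --out results/        # tornado table + figure
etpymodel sens --mode psa --n 1000 --seed 42 --out results/   # CE plane, CEAC
etpymodel init-config --out my_config.yaml      # editable copy of all inputs
```

The same functionality is available as a library
(`etpymodel.run_base_case`, `etpymodel.run_psa`, …); see `docs/methods.md`
for the modelling choices and their rationale.

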