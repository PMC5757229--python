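# Methods

This note documents the model implemented by `etpymodel`: its structure,
assumptions, numerical conventions and the design choices made where the
source material left the design open. It states no result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model structure

The cohort moves through annual cycles over a Markov state space of

* 11 base states: no CVD, established CVD (ECVD), acute MI, acute ischaemic
  stroke (IS), acute heart failure (HF), post-MI, post-IS, post-HF, CHD
  death, IS death, non-CVD death;
* 11 composite chronic states — every size-≥2 subset of the four chronic
  memory flags {ECVD, post-MI, post-IS, post-HF}. (The source description
  counts thirteen composites; the four named flags yield eleven size-≥2
  subsets and the two additional states are not identifiable from the text,
  so the subset design is used and the discrepancy is recorded rather than
  guessed.)
* acute states additionally enumerate the full memory set they will deposit:
  a patient with a prior stroke who suffers an MI spends one cycle in
  `acute_mi[post_mi+post_is]` and then settles in the {post-MI, post-IS}
  composite. This keeps event memory intact through the acute year and is
  what makes the composite bookkeeping exact (43 states in total).

Composite states transition at the highest member risk and are costed at the
highest member cost (costs are never added, which would overestimate).
Revascularisation is a procedure, not a state: an annual procedure rate is
applied to ECVD, acute-MI and post-MI occupancy (memory-carrying states take
the highest applicable member rate).

**Within-cycle sequencing.** Non-CVD death is resolved first; survivors
experience at most one CVD event per cycle. The any-event annual rate is
converted to a probability (`1 − exp(−rate)`), split across MI/IS/HF/CV
death by the prior-event context's event-distribution row, and CV death is
split into IS death versus CHD death by the context's cerebrovascular
fraction. Acute states last exactly one cycle. These conventions prevent
double counting; the dwell time and single-event rule follow standard
annual-cycle cohort practice.

**Trace.** Occupancy is propagated by matrix multiplication; person-time and
occupancy-based costs use the trapezoidal half-cycle correction (mean of
start- and end-of-cycle occupancy); incidence-based quantities attach at the
transition. The lifetime horizon stops at age 110 or when alive mass falls
below 1e-6. The trace is fully deterministic.

## Baseline risk

* **Primary prevention (no-CVD state).** A 10-year risk score evaluated at
  the cohort's mean covariates, annualised under a constant hazard
  (`rate = −ln(1−p)/10`).
* **Secondary prevention.** A 20-month "next cardiovascular event" score per
  post-event state, with prior-event indicator covariates and a region
  coefficient for Eastern Europe / Middle East (on by default), annualised
  the same way.
* **Age-effect removal.** Both equations are frozen at the baseline age by
  absorbing the age term into the intercept and zeroing the age coefficient
  (idempotent, exact at the baseline age). The cohort still ages through the
  life table, so background mortality stays realistic while CVD risk does
  not compound with age — the stated intent of the age-removal methodology.
  Because risks are age-frozen, evaluating the 20-month score at entry or
  per cycle is equivalent; it is fixed at entry.
* **FH adjustment.** The excess risk of FH versus other hyperlipidaemic
  patients enters as a pooled rate ratio, default 7.1 (95 % CI 5.7–8.7),
  applied multiplicatively to every predicted rate. A computation mode
  converts the underlying case-control odds ratios (13.2 off / 10.3 on
  therapy) to risk ratios via `RR = OR/(1−p₀+p₀·OR)` at a configurable
  reference risk and pools them by the treated share; the published 7.1 is
  the packaged default because the original pooling weights are not printed.
* **Calibration.** A single multiplicative scalar on the primary-prevention
  rate is chosen jointly with the FH adjustment so the no-CVD state's final
  annual rate equals `−ln(1−0.55)/10`, reproducing the 55 % 10-year ≥1-event
  target exactly. The trace-based recovery check measures the *net*
  (non-CVD-mortality-deleted) first-event risk, which is what a risk
  equation predicts.

**Risk ↔ rate conversions** assume a constant hazard within each horizon —
the standard choice for annual-cycle Markov CEA.

## Treatment effect

`rate_treated = rate_baseline × RR^ΔLDL-C` with ΔLDL-C in mmol/L
(`relative reduction × baseline LDL-C / 38.67`; 0.6131 × 155.46 / 38.67 =
2.4648 mmol/L). This power form is the only one consistent with "per
1 mmol/L" rate ratios; an 18 % per-mmol reduction compounds to ≈ 38 % at the
trial's ΔLDL-C. Per-event ratios: MI 0.71, IS 0.69, CHD death 0.80
(99 % CIs), revascularisation 0.66 (95 % CI); IS death fixed at 1; no effect
on HF. Inside the engine each state's any-event rate is decomposed into
per-event rates by its context row, each scaled by its ratio, and
recombined — so the treated event *mix* shifts as well as the level. The
ECVD table row is declared "equivalent to MI" and therefore acts through the
MI ratio. The revascularisation effect applies to ECVD and post-MI
occupancy but not to acute-MI revascularisation, which is mediated by the
reduced MI incidence itself. The effect is constant over lifelong treatment;
a finite treatment duration (used in sensitivity analysis) reverts the
treated arm to control dynamics, drug cost and attainment afterwards.

## Mortality

Non-CVD mortality comes from a life table by age and sex with a CVD cause
fraction (IHD I20–I25 + cerebrovascular I60–I69). The cause-deleted annual
probability uses the competing-risk convention
`q_noncvd = 1 − (1−q_all)^(1−frac)`, which remains a valid probability at any
`q_all`; the naive subtraction `q_all·(1−frac)` is available as a config
switch. The trace is one cohort, not sex-stratified: probabilities are
weighted by the female fraction (the alternative — stratified traces — is
not described by the source and is out of scope; the weighted table is the
default documented behaviour).

## Economics

Costs (BGN, 2015, payer perspective): acute year-1 costs at incidence (MI
7,384.10; IS 4,154.84; HF 2,569.28), one-off death costs at fatal incidence
(CHD death 5,171.50 — a 28.3/56.6/15 mixture of fatal UA/MI/HF; IS death
8,095.00), revascularisation 5,498.92 per procedure (78.5 % PCI / 21.5 %
CABG), post-event annual costs on chronic occupancy (ECVD and post-MI
582.05; post-IS 223.03; post-HF 2,564.61; composites at the highest member
cost), and annual drug costs on alive person-time. Category sums are kept
exact to the total (a conservation test enforces 1e-6 BGN).

Discounting: 5 %/year on costs and outcomes, cycle 1 undiscounted, factor
`1/(1+r)^(t−1)` on trapezoid-averaged quantities. Event counts are reported
undiscounted; LYs, ETPYs and costs discounted. The ICER is reported only
when the intervention is both costlier and more effective; otherwise a
dominance flag is set.

## Sensitivity analysis

* **Distributions.** Beta for the LDL-C reduction and the attainment
  proportions (method of moments from mean and SE, SE from the 95 % CI);
  gamma for every health-state cost (`shape = (mean/SE)²`,
  `scale = SE²/mean`, SE = 10 % of the mean); lognormal for the rate ratios
  and the pooled FH ratio, with `σ = (ln hi − ln lo)/(2z)` at the CI's own
  level (z = 2.576 for the 99 % intervals) and the location chosen so the
  distribution's *mean* equals the point estimate
  (`μ = ln(mean) − σ²/2`) — mean-matching keeps the Monte Carlo parameter
  means unbiased, which the recovery tests verify. The IS-death ratio is
  fixed and never sampled; the ECVD row is not sampled separately because
  its effect runs through the MI ratio.
* **One-way analysis.** Each uncertain parameter is set to the 2.5th and
  97.5th percentile of its fitted distribution; structural scenarios set
  either discount rate to 0 % and the treatment duration to 5 years. Rows
  are sorted by absolute ICER deviation; undefined-ICER scenarios are
  flagged, not dropped.
* **PSA.** Independent sampling (no correlation structure is described for
  these inputs), 1,000 iterations by default, full pipeline per draw,
  reproducible by seed; out-of-support draws are resampled, not truncated,
  with an audit count. The headline PSA ICER is the ratio of means; the
  per-iteration draws (and a CEAC) are exported alongside.

## Synthetic inputs: what they emulate and what they do not

Four inputs are under-published and shipped as deterministic synthetic
stand-ins (all labelled synthetic, all replaceable via config):

* **Life table** — Gompertz–Makeham hazards (`q = 1 − exp(−(a + b·cᵃᵍᵉ))`)
  with sex factors 0.7/1.3 and a logistic CVD-death-fraction ramp, chosen
  once for Eastern-European magnitudes (≈ 0.5 %/year at age 51, 6–9 % at 85).
* **Risk-equation coefficients** — logistic-link sets with conventional
  covariates and sign structure, with intercepts placed so the uncalibrated
  10-year primary risk is ≈ 8 % and the 20-month secondary risks ≈ 5–8 %
  before the FH adjustment.
* **Event-type distribution** — template multinomial rows (recurrence
  concentrates on the prior event type; CV death ≈ a fifth to a quarter of
  events) with small seeded lognormal jitter; composite rows are the
  renormalised element-wise maximum of member rows, mirroring the
  maximum-risk rule.
* **Drug costs** — evolocumab 10,650 BGN/year and statin 128 BGN/year,
  consistent with published Bulgarian reimbursement magnitudes.

Because these stand-ins are plausible rather than estimated, passing tests
demonstrate the *correctness of the machinery* (conservation, calibration,
oracle agreement, effect arithmetic, dominance and discounting behaviour)
and realistic orders of magnitude — not a reproduction of any particular
published table computed from the true unpublished inputs.

## Numerical conventions and degenerate inputs

Row-stochasticity is enforced to 1e-9 (violations raise, naming the state);
occupancy rows must sum to 1 within 1e-9 with non-decreasing death mass;
probabilities are validated to [0, 1]; `p = 1` is rejected in risk→rate
conversion (infinite rate); zero total event rate short-circuits the event
split; event-distribution rows are renormalised idempotently (bit-identical
when already normalised, which keeps config round-trips exact); CSV IO uses
`%.17g` and round-trip float parsing. Ties in the composite maximum rule are
harmless (`max` of equal rates). Seeds are mandatory for every stochastic
entry point.

## Validation strategy

A 200,000-individual microsimulation steps through the identical transition
matrices and must agree with the cohort trace within Monte Carlo error at
every cycle; because ~2,500 (cycle, state) cells are compared
simultaneously, the bound is the Šidák-corrected 3-sigma envelope with the
per-cell 3-SE exceedance count additionally held to its own binomial noise
bound, and cells with probability exactly 0 or 1 must match exactly.
Conservation, null-effect symmetry (zero ΔLDL-C and equal attainment leave
only the drug bill), treatment-effect arithmetic to 1e-12, calibration
recovery to 0.5 percentage points, PSA degeneracy/convergence and the
discounting direction checks complete the acceptance surface; problem sizes
are the model's own (59 lifetime cycles, 50 randomised configurations, 1,000
PSA iterations).

## Known limitations

Cohort-level (mean-covariate) risk prediction, no individual heterogeneity
in production traces; no adherence/persistence or waning-efficacy
modelling; no adverse-event or indirect costs; independent PSA parameters;
single-cohort (sex-weighted) mortality; the synthetic stand-ins above. The
two unidentifiable extra composite states are documented rather than
invented.
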