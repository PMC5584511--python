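# Methods

## Model and scope

The package implements the aggregate proximate-determinants model of
fertility: TFR = TF·Cm·Cc·Ca·Ci, with the index of marriage
Cm = Σ m(a)g(a)/Σ g(a), the index of contraception Cc = 1 − 1.08·u·e
with e = Σ e(i)u(i)/u, and the index of postpartum insusceptibility
Ci = 20/(18.5 + i). The analysis universe is currently married women of
reproductive age (consensual unions count as married), the setting the
classical model assumes; the sexually-active-universe reformulation is
deliberately out of scope. The abortion index Ca is fixed at 1: DHS-type
surveys carry no abortion incidence data, so no inhibitory effect is
attributed to it. Change between surveys is decomposed through the ratio
identity TFR₂/TFR₁ = Π (index ratios) · R₂/R₁ into proportional
components plus an interaction term defined as the additive closure
P_f − (P_m + P_i + P_c + P_r). Closure is always computed that way
rather than from the analytic product expansion, so the identity still
holds when a user supplies externally rounded index values.

## Constants and parameters

| parameter | default | units | meaning |
|---|---|---|---|
| TF | 15.3 | births/woman | total fecundity; empirical range 13–17, warning outside |
| sterility adjustment | 1.08 | — | zeroes Cc at effective prevalence 1/1.08 ≈ 92.5% |
| birth interval, no insusceptibility | 20 | months | numerator of Ci |
| interval base | 18.5 | months | 7.5 waiting + 2 intrauterine mortality + 9 gestation |
| e(i) | pill 0.90, IUD 0.95, sterilization 1.00, condom 0.62, other 0.70, injectable 1.00, implant 1.00 | — | use-effectiveness |
| ASFR window | 36 | months | retrospective fertility window before each interview |
| min m for g | 0.01 | proportion | stability threshold for g(a) = f(a)/m(a) |

Injectables and implants are long-acting hormonal methods with near-zero
failure in use; they are assigned effectiveness 1.00 rather than being
folded into "other" at 0.70. The table is overridable in the YAML
config; with 0.70 the 2005 Amhara index would be 0.87 instead of 0.83.

## Estimators

**Age-specific fertility.** Dates are exact month counts on
century-month codes (CMC, months since January 1900), ages in completed
months, age groups half-open [a, a+5). Each woman's exposure over the
36 months before her own interview is split exactly across the age
groups she passes through; a birth is classified by the mother's age at
the birth. Exposure and births outside [15, 50) are excluded.
The 36-month window is the convention under which DHS reports publish
three-year rates. A zero-exposure group reports f(a) = 0 with a logged
warning. On fixtures of ≤ 10 women the implementation is tested for
exact equality against an independent month-by-month brute-force ledger.

**Marriage proportions.** Weighted proportion currently married per age
group at interview; an empty group is flagged missing (NaN), never 0.

**Contraception.** Weighted prevalence of any modern method and the
per-method mix among currently married women; mix values are normalised
to sum to u exactly (removing float drift) so the downstream weighted
average is well defined.

**Postpartum insusceptibility.** Default estimator is the
prevalence/incidence ratio i = P/B: current-status count of
amenorrheic-or-abstaining women among mothers with a birth in the
window, over mean monthly births in the window. Under a stationary birth
flow this equals the mean spell duration (Little's law). A
current-status-sum estimator (Σ over months-since-last-birth of the
proportion still insusceptible) is selectable; the two agree on
stationary synthetic data but neither is asserted to reproduce published
durations beyond tolerance, since survey reports do not state their
estimator. Missing postpartum flags are treated as not insusceptible and
logged.

**Unstable young-age marital fertility.** When f(15–19) > 0 but
m(15–19) < 0.01, g(15–19) is imputed as 0.75·g(20–24) (configurable:
impute/drop/error), the standard correction for the small-denominator
instability of g(a) at young ages.

Weighted estimation is the default; all estimators are invariant to
rescaling all weights by a positive constant, and weighted tallies are
additive across any partition into strata. An unweighted mode exists for
hand-count oracle tests.

## Synthetic data generator

The generator emulates the survey conditions the published aggregates
describe; its defaults are the 2011 Amhara totals (u = 0.330, the
published method mix among users, i = 19.0 months) with an
early-marriage age schedule m(a) = (0.45, 0.80, 0.90, 0.92, 0.90, 0.85,
0.80), chosen to reflect a median age at first marriage near 15 and
near-universal marriage by the late twenties; marriage proportions by
age are not published, so this schedule is a fixed modelling choice.
Each woman's age is uniform over [15, 50) in months; union status and
method use are drawn at interview-age probabilities and held fixed over
the simulated history. While married, aged 15+, not pregnant and not
insusceptible, she conceives with monthly probability 0.20·(1 − e(i));
gestation is nine months; each birth opens an insusceptible spell drawn
from min(Exponential(s), 36) with the scale s solved numerically so the
realised mean equals the configured i exactly (a pure conditional
truncation at 36 could not even reach a mean of 19). Spell lengths are
rounded to whole months unbiasedly (floor plus Bernoulli on the
fraction). Sixty burn-in months precede the emitted 60-month history so
the birth flow is stationary inside the estimation window; weights
are 1.

True index values for recovery tests follow from the configuration:
Cc and Ci by their closed forms, and Cm as the unweighted mean of
m_by_age, since a single fecundability constant makes the marital
fertility schedule approximately flat in age. The generator does **not**
emulate: age-varying fecundability or sterility, union formation and
dissolution over the history, contraceptive discontinuation, abortion,
or clustered sampling with non-unit weights. Consequently its natural
fertility level (≈ 28 births/woman at fecundability 0.20) exceeds the
empirical total fecundity of 15.3, which bundles age-related
subfecundity and intrauterine mortality; the multiplicative-closure
check therefore compares simulated fertility against the simulated
population's own natural-fertility level (a companion run with u = 0,
i = 1.5, m ≡ 1), where the indices predict fertility within a factor
[0.7, 1.4]. Passing recovery tests show the estimators and index
formulas are correct on data satisfying the model's assumptions; they do
not certify behaviour under real-data features such as birth
displacement, age heaping or recall error.

## Numerical choices

- All computation is full precision; rounding (half-up; indices and MTFR
  to 2 decimals, percentages to 1) happens only in the reporting layer.
- Cc is clipped at 0 with a warning when u·e exceeds 1/1.08; Ci is
  capped at 1 inside the pipeline when i < 1.5 months (index semantics);
  Cm above 1 (possible only through imputation pathologies) is clipped
  with a warning.
- The decomposition's additive identity is exact up to one floating-point
  rounding of the re-summation (≤ 1e-12); the reversal identity
  (1+P_f(a,b))(1+P_f(b,a)) = 1 holds to the same tolerance.
- Undefined situations raise typed errors rather than returning
  sentinels: no births in the insusceptibility window, zero prevalence
  in the effectiveness average, a zero index in a residual or
  decomposition denominator, every fertile group unstable in Cm.
- Deterministic output: the generator is a pure function of
  (config, seed), and CSV serialisation uses fixed formatting, so
  identical runs are byte-identical.

## Known limitations and documented discrepancies

- Published model-TFR levels are not asserted anywhere: the printed
  values are not the product of the printed (rounded) indices with
  TF = 15.3 (e.g. 15.3·0.71·0.49·0.93 = 4.95 against a printed 5.50 for
  2000), which indicates they were computed from unrounded intermediate
  values that were not published. The package computes the product
  exactly.
- Ci from the published 2011 mean duration of 19.0 months is 0.533; the
  source table prints 0.54, consistent with an unrounded duration
  slightly below 19. The package asserts agreement within ±0.01 for that
  cell and exact 2-decimal agreement for 22.6 → 0.49 and 21.4 → 0.50.
- The published 2000 method-mix percentages sum to 6.7 while the printed
  prevalence is 6.6; the bundled aggregates rescale the mix
  proportionally. Cc is unaffected at two decimals.
- Decomposition components recomputed from rounded published indices
  differ in the last decimal from the published component table (whose
  inputs were unrounded); only the total-change rows, which follow from
  the published model TFRs, are asserted.
- The prevalence/incidence estimator assumes a stationary birth flow
  over the window; it is biased under strong fertility trends or
  seasonality within the window.
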