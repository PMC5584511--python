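# proxdet — proximate determinants of fertility

`proxdet` implements the Bongaarts proximate-determinants model as a
reusable, tested pipeline: from DHS-style woman-level microdata to the
indices of marriage, contraception and postpartum insusceptibility, the
model total fertility rate, and the decomposition of fertility change
between two surveys into determinant-specific components, with
stratification by residence or education. It is aimed at demographers and
reproductive-health analysts who want these calculations reproducible
from flat CSV extracts instead of spreadsheets.

## The model

Total fertility is written as a product of total fecundity and four
fertility-inhibiting indices, each in [0, 1] (1 = no inhibition):

```
TFR = TF · Cm · Cc · Ca · Ci
```

- **Cm = Σ m(a)·g(a) / Σ g(a)** — index of marriage, where m(a) is the
  proportion of women in five-year age group *a* currently married
  (including consensual unions) and g(a) = f(a)/m(a) is the age-specific
  marital fertility rate.
- **Cc = 1 − 1.08·u·e** — index of contraception, where *u* is modern
  contraceptive prevalence among currently married women 15–49 and
  *e* = Σ e(i)·u(i)/u is prevalence-weighted mean use-effectiveness
  (pill 0.90, IUD 0.95, female sterilization 1.00, male condom 0.62,
  other 0.70; injectables and implants 1.00 by default, overridable).
  The 1.08 factor removes infecund couples, so the index reaches zero at
  an effective prevalence of 92.5%.
- **Ci = 20 / (18.5 + i)** — index of postpartum insusceptibility, where
  *i* is the mean duration (months) of postpartum amenorrhea or
  abstinence; 20 and 18.5 months are the average birth intervals without
  and with minimal (1.5-month) insusceptibility.
- **Ca** — index of induced abortion, fixed at 1 (no survey data).
- **TF ≈ 15.3** births per woman, the empirical total fecundity level.

Change between two surveys decomposes through the ratio identity
TFR₂/TFR₁ = (Cm₂/Cm₁)(Ci₂/Ci₁)(Cc₂/Cc₁)(R₂/R₁) into proportional
components P_m, P_i, P_c, a residual P_r, and an interaction term I that
closes the additive identity P_f = P_m + P_i + P_c + P_r + I exactly.

The estimators that feed the model (age-specific fertility rates from
birth histories in century-month codes, marriage proportions,
prevalence/method mix, mean insusceptibility via the
prevalence/incidence ratio) live in `proxdet.aggregation`; a seeded
microsimulation with known true parameter values (`proxdet.simulate`)
backs end-to-end parameter-recovery tests.

## Worked example

The published survey aggregates for currently married women 15–49 in
Amhara National Regional State (2000/2005/2011 Ethiopia DHS) ship with
the package:

```python
from proxdet import compute_cc, compute_ci, compute_e, round_half_up
from proxdet.amhara import SURVEYS, contraception_inputs

for year in ("2000", "2005", "2011"):
    s = SURVEYS[year]
    u, mix = contraception_inputs(year)
    e = compute_e(mix, u)
    cc = compute_cc(u, e)
    ci = compute_ci(s.insusceptibility_months)
    print(f"{year}: u={u:.3f}  e={e:.4f}  Cc={cc:.4f} ({round_half_up(cc,2):.2f})"
          f"  Ci={ci:.4f} ({round_half_up(ci,2):.2f})")
```

```
2000: u=0.066  e=0.9552  Cc=0.9319 (0.93)  Ci=0.4866 (0.49)
2005: u=0.157  e=0.9743  Cc=0.8348 (0.83)  Ci=0.5013 (0.50)
2011: u=0.330  e=0.9938  Cc=0.6458 (0.65)  Ci=0.5333 (0.53)
```

Contraception moved from a negligible brake on fertility (Cc = 0.93) to
the dominant one (0.65) as prevalence rose from 6.6% to 33.0%, while the
inhibiting effect of postpartum insusceptibility weakened (Ci rose from
0.49 toward 0.53) as mean durations shortened from 22.6 to 19.0 months.

Decomposing the 2000→2005 change in the model TFR from the index values:

```python
from proxdet import IndexSet, decompose

idx1 = IndexSet(cm=0.71, ci=0.49, cc=0.93, ca=1.0, tf=15.3, mtfr=5.50, label="2000")
idx2 = IndexSet(cm=0.73, ci=0.50, cc=0.83, ca=1.0, tf=15.3, mtfr=5.12, label="2005")
for factor, pct in decompose(idx1, idx2).as_percent().items():
    print(f"{factor:>13}: {round_half_up(pct, 1):+.1f}%")
```

```
     Marriage: +2.8%
          PPI: +2.0%
Contraception: -10.8%
     Residual: +0.0%
  Interaction: -1.0%
         MTFR: -6.9%
```

The 6.9% fertility decline over 2000–2005 is driven by contraception
(−10.8%), partly offset by rising marriage (+2.8%) and shortening
postpartum insusceptibility (+2.0%); negative signs mark inhibiting
determinants.

## Command line

The same pipeline is available as a CLI (`proxdet simulate | aggregate |
indices | decompose | recover`), e.g.:

```sh
proxdet simulate --seed 42 --n-women 8000 --out-dir sim/
proxdet aggregate sim/women.csv sim/births.csv --survey-label 2011 --out inputs.json
proxdet indices inputs.json --out-dir out/
proxdet decompose out/indices.json --pairs 2000:2005,2005:2011 --out table3.csv
```

Every command writes a manifest (input digests, config echo, seed,
warnings); exit codes are 0 (success), 1 (computation error), 2
(input/validation error).

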