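# ironavail

Population-level estimation of **dietary iron bioavailability** — the
percentage of ingested iron that is absorbed — for adult population groups,
from individual iron intakes and serum ferritin (SF) concentrations.

Bioavailability factors are needed to turn physiological (absorbed-iron)
requirements into dietary reference values, but fractional iron absorption
cannot be measured directly in surveys. This package implements a
prevalence-matching model: given a nutrition-survey cohort and an
absorbed-iron requirement distribution, it computes the dietary absorption
consistent with the group's observed iron-status distribution. It is aimed
at nutrition scientists and risk managers deriving dietary recommendations
from survey data.

## The model

For a group of $n$ individuals with daily iron intakes $x_i$ (mg/d) and an
absorbed-iron requirement distribution given by its quantile function
$R(p)$ (mg/d at population percentile $p$, on the half-percentile grid
$p = 0.5, 1.0, \dots, 99.5$):

1. **Predicted prevalence of inadequacy.** At an assumed absorption
   $a$ (%), individual $i$ absorbs $x_i \, a/100$ mg/d. The probability
   this fails to meet requirements is the fraction of the 199 grid points
   with $R(p) > x_i\,a/100$ (the full-probability approach; a requirement
   exactly met counts as adequate). Averaging over individuals and scaling
   by 100 gives the predicted prevalence $\pi(a)$, evaluated along the
   absorption scale $a = 1, 1.5, \dots, 40$ %. $\pi$ is non-increasing
   in $a$ by construction.
2. **Observed prevalence of insufficiency.** For an SF cutoff $S$
   (e.g., 15 µg/L, depleted stores), $P_{\mathrm{obs}}(S)$ is the percent
   of the group with SF strictly below $S$. Individuals with raised
   inflammation markers (hs-CRP > 5 mg/L or α‑1‑antichymotrypsin
   > 0.65 g/L) and iron-supplement users are excluded first, since their
   SF or intake data would bias the match.
3. **Prevalence matching.** The estimated dietary absorption at SF level
   $S$ is the $a$ solving $\pi(a) = P_{\mathrm{obs}}(S)$, found by linear
   interpolation on the monotone curve (out-of-range targets clamp to the
   grid endpoint and are flagged). All analyses are stratified into men,
   premenopausal and postmenopausal women.

The estimate is population-level by design; no individual absorption
values are produced. Published requirement percentile tables are consumed
as CSV inputs; for testing without external data, the package generates
synthetic lognormal requirement distributions and survey-like cohorts
(moment-matched lognormal intake and SF marginals).

## Worked example

```python
import ironavail as ia

spec = ia.GroupSpec(group="premenopausal", n=5000, intake_mean=10.3, intake_sd=4.1,
                    sf_mean=49.4, sf_sd=45.8, seed=42)
cohort = ia.generate_group(spec)
requirements = ia.generate_requirement_distribution(
    ia.default_requirement_spec("premenopausal"))

intakes = [ind.iron_intake for ind in cohort]
print(f"prevalence of inadequacy at 18% absorption: "
      f"{ia.predicted_prevalence(intakes, requirements, 18.0):.1f}%")

profile = ia.absorption_profile(cohort, requirements, [15, 30, 60])
for cutoff, a in zip(profile.sf_cutoffs, profile.absorption):
    print(f"estimated absorption at SF < {cutoff:.0f} ug/L: {a:.1f}%")
```

prints

```
prevalence of inadequacy at 18% absorption: 37.6%
estimated absorption at SF < 15 ug/L: 31.9%
estimated absorption at SF < 30 ug/L: 17.3%
estimated absorption at SF < 60 ug/L: 9.3%
```

Read: if premenopausal women in this (synthetic) population absorbed 18%
of dietary iron, 37.6% of them would not meet their absorbed-iron
requirement. Matching predicted to observed prevalence, the diet of women
maintaining SF just below 15 µg/L supplies iron at ~32% absorption, while
at a replete SF of 60 µg/L only ~9% absorption is consistent with the
data — absorption is down-regulated as stores fill, and the estimated
values fall monotonically with the SF cutoff.

The same computation is available from the shell:

```bash
ironavail simulate --seed 42 --out-dir sim/
ironavail filter --cohort sim/cohort_NANS.csv --cohort sim/cohort_NDNS.csv \
    --cohort sim/cohort_NU-AGE.csv --out-dir filtered/
ironavail absorption --cohort filtered/filtered_cohort.csv \
    --requirements men=sim/requirements_men.csv \
    --requirements premenopausal=sim/requirements_premenopausal.csv \
    --requirements postmenopausal=sim/requirements_postmenopausal.csv \
    --out-dir results/
```

Every command writes CSV outputs plus a JSON manifest (inputs, config
hash, version) sufficient to re-run bit-identically.

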