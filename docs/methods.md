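# Methods

## Model and assumptions

`ironavail` estimates population-level dietary iron absorption by
prevalence matching. Two empirical facts about a group are combined:

- the distribution of daily iron intakes $x_i$ (mg/d, heme + nonheme,
  measured by diet records), and
- the distribution of serum ferritin (SF, µg/L), a quantitative marker of
  body iron stores,

together with one external piece of physiology: the distribution of
absorbed-iron requirements across the population, represented by its
quantile function $R(p)$ on the half-percentile grid
$p = 0.5, \dots, 99.5$ (199 points).

At an assumed absorption $a$, the probability that individual $i$'s
absorbed iron $x_i a / 100$ fails to meet requirements is evaluated as a
step function over the grid: the fraction of grid points with
$R(p) > x_i a / 100$ (ties — requirement exactly met — count as adequate,
so the probability is 0 at the top grid value). The mean over individuals,
times 100, is the predicted prevalence of inadequate intakes $\pi(a)$,
computed along the absorption scale 1–40 % in 0.5 % steps. This is the
full-probability approach to nutrient adequacy; it assumes intake and
requirement are independent at the individual level, which is the standard
assumption for iron (requirements are dominated by basal and menstrual
losses, not by intake).

The identifying assumption is that the prevalence of inadequate intakes
equals the observed prevalence of iron insufficiency: the percent of the
group with SF strictly below a chosen cutoff. Inverting the monotone curve
$\pi(a)$ at that observed prevalence yields the absorption estimate. The
model is deliberately population-level: a single absorption value per
group and SF cutoff, not per-individual predictions, and it supersedes
algorithmic diet-composition approaches (heme fraction,
enhancers/inhibitors), which are out of scope.

## Key parameters

| parameter | default | units | notes |
|---|---|---|---|
| absorption grid | 1–40, step 0.5 | % | configurable (`grid_min/max/step`); 0 allowed as lower bound for plotting |
| requirement grid | 0.5 … 99.5 | percentile | 199 points; coarse tables are interpolated |
| CRP threshold | 5 (strict >) | mg/L | inflammation exclusion |
| ACT threshold | 0.65 (strict >) | g/L | inflammation exclusion (surveys that measured ACT instead of CRP) |
| SF cutoffs | 15, 20, 30, 40, 50, 60, 80, 100 | µg/L | strict `<`; SF exactly at the cutoff counts as sufficient |

## Numerical choices

- **Interpolation of requirement tables**: piecewise-linear in the
  percentile domain (monotone by construction on monotone input); a
  monotone-cubic (PCHIP) option exists behind `method="pchip"`. Fine
  percentiles outside the coarse table's span are clamped flat to the
  nearest endpoint with a warning — no tail behavior is invented. A
  cumulative-maximum guard removes any round-off dips.
- **Inversion**: linear interpolation between the two bracketing grid
  points of the prevalence curve. If a flat stretch ties the target
  exactly, the smallest absorption is returned (the least absorption
  consistent with the data). Targets above the curve's maximum or below
  its minimum clamp to the grid endpoint and carry an explicit flag; no
  extrapolation beyond the scale.
- **Exclusion pipeline order** is fixed — inflammation, then supplement
  users, then missing SF — and the report records sequential (not
  marginal) counts, so counts always sum to the input size. Individuals
  with neither inflammation marker measured are retained: absence of
  evidence keeps them in (configurable thresholds; a survey that measured
  only ACT is handled by the OR rule).
- **Scales**: percentages are carried 0–100 end-to-end; probabilities 0–1
  only inside `probability_of_inadequacy`. Sample SDs use the n−1
  denominator; rounding to one decimal happens only at reporting time.
- **Degenerate inputs**: empty cohorts, non-monotone requirement tables,
  unclassified women (menopausal status is an input, never imputed from
  age) and missing SF at CDF time are hard errors, not silent fixes.

## Synthetic data: what it emulates and what it does not

The generator draws intake and SF from lognormal laws moment-matched to
target arithmetic means and SDs, so published group means ± SDs can be
used directly as specs; both variables are strongly right-skewed in
surveys (group SF SDs approach their means, ruling out symmetric laws).
An optional Gaussian copula (Spearman correlation mapped to the latent
Pearson correlation via $r = 2\sin(\pi\rho_s/6)$) can couple intake and
SF; the default is 0, matching the model's assumption of no
individual-level link. Inflammation markers are drawn so the specified
fraction exceeds the exclusion threshold; supplement use is Bernoulli. A
single integer seed determines all draws through named substreams, so
adding a field never perturbs existing ones. The NDNS supplement-use rate
is not published; 0.10 was chosen once, between the two known survey
rates.

`generate_consistent_scenario` embeds a ground-truth absorption $A^*$:
intakes are drawn, the predicted prevalence $P^*$ at $A^*$ is computed,
and SF values are assigned so that exactly $\mathrm{round}(nP^*/100)$
individuals fall strictly below the cutoff (below/above values are the SF
law's quantiles conditioned on each side, randomly assigned). Recovery
experiments (n = 5000, $A^* \in \{5,10,18,25,35\}$ %, 50 seeds each)
recover $A^*$ well within one grid step (0.5).

Synthetic requirement distributions are lognormal quantile functions —
parametric stand-ins for published percentile tables, with medians near
published dietary average requirements (≈6–7 mg/d) times a nominal 16 %
absorption: men 1.05 mg/d (log-SD 0.25), premenopausal women 1.40 mg/d
(log-SD 0.55, the widest, reflecting menstrual-loss variability),
postmenopausal women 0.95 mg/d (log-SD 0.25).

What passing tests on synthetic data show: the estimator is correct and
stable under the model's own assumptions. What they do not show: that any
real population satisfies those assumptions, or that absolute absorption
values computed with the synthetic requirement tables match values
computed with real published tables — for that, supply the real survey
records and requirement CSVs. Real-data features not emulated include
survey weighting and design effects, intra-individual intake variation
(diet-record noise), assay differences between surveys, and longitudinal
SF dynamics.

The recovery experiments use premenopausal-women specs because that
group's wide requirement distribution keeps the prevalence curve strictly
decreasing across the whole 1–40 % scale; in groups with narrow
requirements the curve saturates at 0 % below high absorption values, and
an embedded truth in the saturated region is unidentifiable (the inversion
then returns the smallest absorption on the flat stretch, flagged where
clamped).

## Design choices where the design was open

- The "average absorption for the population" is implemented as the
  absorption returned by prevalence matching — a population-level match,
  not a mean of per-individual values (which the model never produces).
- Observed prevalence defaults to the pooled (combined-study) group;
  per-study runs are available by passing a single cohort file.
- Exclusion thresholds are strict inequalities (CRP = 5 mg/L retained).
- Requirement tables are input data; their factorial derivation from
  basal/menstrual losses is out of scope.
- Plots are optional artifacts; all results rest on CSV values.

## Problem sizes

Tests and the acceptance script use synthetic cohorts of a few hundred to
5000 individuals per group (survey scale), 199-point requirement grids and
the 79-point absorption scale; the full suite runs in well under a minute,
with recovery experiments dominating.

## Known limitations

- Identification fails where the prevalence curve is flat at the observed
  prevalence (very iron-replete groups at low SF cutoffs); such points are
  flagged rather than extrapolated.
- Estimates at a given SF cutoff with few individuals below it inherit
  large sampling noise in the observed prevalence; the package does not
  currently propagate that uncertainty (no confidence intervals).
- Intakes are treated as usual intakes; day-to-day measurement error is
  the caller's responsibility to address upstream.
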