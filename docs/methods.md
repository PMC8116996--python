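# Methods

This note records the models, conventions and numerical choices behind
`inboxstress`, and what the synthetic-data generator does and does not
emulate.

## Time attribution from access logs

Access logs record instants, not durations. Each event opens an interval
that closes at the next event of the same physician or after an idle
cutoff (default 5 minutes), whichever comes first — last-event-carried-
forward, the standard audit-log convention when vendor "active time"
fields are unavailable. Consequences worth knowing:

- an isolated click is always worth one idle cutoff of attributed time;
- attributed time is monotone non-decreasing in the cutoff;
- intervals are half-open `[start, end)`, and hourly bins are anchored at
  :30 past the hour so that bins align with an 8:30 shift start. An event
  exactly on a boundary belongs to the later bin.

Message counts come from task-completion markers on inbox events (logs
carry no message identifiers), so time-per-message is inbox minutes over
completed tasks.

## Temporal split and batching

The workday schedule defaults to 08:30–12:30 and 13:30–17:30,
Monday–Friday. Out-of-shift inbox minutes are *contiguous* when their
activity run — inbox intervals merged across gaps of at most the
contiguity gap (default 60 min) — comes within that gap of a shift
boundary, else *noncontiguous*. Neither the block gap nor the contiguity
gap has a canonical value in the literature; both are config-exposed, and
the batching flag is provably non-decreasing in the block gap (merging
more can only concentrate coverage), which the property suite checks.

A day is *batched* when the top 3 blocks (inbox intervals merged across
gaps ≤15 min) cover ≥70% of the day's inbox minutes. Days with no inbox
time are never batched.

## Stress durations and validity

A 3-minute stress sample is classified all-or-nothing by its average
score: >50 contributes 3 stress minutes, 25–50 and <25 contribute valid
but non-stress minutes (ordinary arousal and rest), and samples flagged
for physical activity or missing contribute nothing. Samples straddling an
hour boundary are clipped, splitting their minutes across bins. Hours with
<20 valid minutes and days with <120 are excluded so stress fractions
never ride on sparse denominators; the filter is idempotent and every
removal is reported as (total, removed, %). Summary tables round to whole
percent (half-up); all internal computation is full precision.

## Work-pattern clustering

Physician profiles are the mean daily proportions of inbox time in the
three temporal classes. The Gaussian mixture is fit on all three
proportions with a square-root variance-stabilizing transform on the
noncontiguous share: that share's dispersion grows with its mean (near
zero for in-hours physicians), and in raw space a single wide component
tends to swallow two groups; the transform also breaks the exact
collinearity of the simplex. Component means are reported back on the
proportion scale. Components are mapped to stable labels by behaviour
(group 1 = highest noncontiguous share, group 2 = highest work-hours share
of the rest, group 3 = remainder), since EM component order is arbitrary.
Model selection sweeps K and candidate feature sets and takes the best
silhouette subject to a minimum-group-size floor (default 5); on
three-group synthetic draws this selects K=3 in the clear majority of
replicates but not on every draw — two of the groups genuinely overlap.

Group comparisons use ANOVA when every group passes Shapiro–Wilk and the
set passes Levene (both at α=0.05), Kruskal–Wallis otherwise; posthoc
Tukey HSD or Dunn (rank z with tie correction, Holm-adjusted — implemented
here because no installed package exposes Dunn); chi-square for
categoricals with Yates continuity correction on 2×2 tables.

## Poisson mixed model

Daily work-hours stress minutes are modeled as Poisson counts with
`log(valid work-hours minutes)` as offset and a physician random
intercept. The marginal likelihood is a one-dimensional integral per
physician, computed by adaptive Gauss–Hermite quadrature (15 nodes;
Laplace mode and curvature rescale the node grid per physician) and
maximized by L-BFGS over `(beta, log sigma_b)`; standard errors come from
the numerical Hessian. The fit agrees with `lme4::glmer` (nAGQ=15) to
about 1e-4 on coefficients, standard errors and the random-intercept SD on
test data; log-likelihoods differ by the `y!` constant that lme4 drops.
Continuous covariates are mean-centered (slopes are centering-invariant;
the property suite checks this and offset invariance), binary covariates
are left on the 0/1 scale, weekday enters as Monday–Thursday dummies with
Friday the reference, and variance inflation factors are screened at 5.

Marginal and conditional R² use the latent-scale variance partition:
`var_f = Var(x'beta)`, `var_b = sigma_b²`, and the observation-level
variance `ln(1 + 1/lambda_bar)` by the lognormal approximation with
`lambda_bar` the mean expected count. Model comparison tabulates AIC and
marginal R² and selects minimum AIC. Overdispersion is not modeled (a
negative-binomial check would slot into the same quadrature but is out of
scope); type-I error of the Wald tests on null simulations is ~5–6% at
α=0.05.

## The synthetic cohort

The generator's defaults are the study conditions: 47 physicians in
groups of 10/17/20, 5 workdays and 2 nonworkdays each, 3.5 h (SD 0.69) of
daily EHR time of which ~65 min is inbox work, group temporal-split
prototypes (work-hours share 37/82/62%, noncontiguous 42/1/12%,
contiguous 21/17/26%, with matching SDs), message mix averaging 37%
patient messages, per-message times 0.46/0.35/0.38 min, batching
propensities 0.50/0.06/0.20 (group 3 is not reported anywhere, chosen
once between the two reported extremes), and work-hours stress fractions
33/18/22%.

Design choices that matter:

- **Simplex draws.** Per-physician temporal proportions come from a
  bivariate logistic-normal (additive log-ratio, contiguous share as
  reference) whose means, SDs and correlation are moment-matched to the
  prototype values by quadrature + least squares. A free ALR correlation
  is required: with independent coordinates, the large contiguous-share
  variance forces excess variance in the in-hours share through the
  shared denominator, making the target dispersions unreachable.
- **Attribution-aware event layout.** Activity is placed as contiguous
  runs of inbox / other-EHR segments; the final event of each run sits one
  idle cutoff before the run end and runs are separated by at least the
  cutoff, so the sessionized duration of a run equals its designed span
  and the pipeline recovers configured minutes to <0.05 min/day. Event
  density and window-id novelty are set so the window-switch rate lands in
  the observed 4–4.5 per EHR minute.
- **Blocks and batching.** Batched days concentrate inbox work in ≤3
  blocks; non-batched days sprinkle in-hours snippets between charting
  runs and spread after-hours work over several modest blocks. Small
  noncontiguous residues pool across days into an occasional evening block
  (physicians with 2–3 evening minutes per day check their inbox on some
  evenings, not every evening) — placing them daily would erase the
  noncontiguous signature that separates the clusters.
- **Stress curve.** Stress probability over clock time is a logistic
  function of three Gaussian bumps (circa 9:00, 13:45, 20:00) over a
  circadian night dip, plus a physician random intercept (SD 0.8 on the
  logit scale). Two calibration constants are solved numerically at
  generation time: per-group offsets pin each group's work-hours stress
  fraction to its prototype, and a global wave amplitude pins the cohort
  first-work-hour mean to 35%.
- **Missingness.** Three mechanisms: contiguous device-off episodes
  (charging, forgotten device), "poor wear" episodes in which samples are
  thinned to ~15% (loose skin contact — the mechanism that actually
  produces hours with 1–19 valid minutes for the hourly filter), whole
  days without wear (p=0.15), and 5 physicians with total device failure.
  Defaults remove ~12% of hours at the 20-minute filter and retain ~180
  model days.

What the generator does **not** emulate: real within-physician day-to-day
autocorrelation of usage (days vary independently around a physician
mean), any causal coupling between usage covariates and stress (stress
depends on group and clock time only, so association-model recovery is
tested on a separate simulator with known coefficients), appointment
structure, and vendor-specific log semantics. Passing calibration tests
therefore shows that the pipeline measures faithfully under the study's
statistical structure — not that the study's substantive associations
would replicate on real data.

## Problem sizes

Simulation-based tests use sizes chosen for tight-but-cheap inference:
calibration recovery pools eight replicate 47-physician cohorts; cluster
recovery averages eight prototype draws; GLMM recovery uses 40 physicians
× 5 days; the null type-I simulation uses 200 fits of 25 physicians × 6
days; AIC model selection uses 50 replicates. The acceptance script
averages three cohort replicates (plus one 40-physician single-group
cohort for per-message time) and runs in well under a minute.
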