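# Methods

## The frailty index

The package builds a deficit-accumulation frailty index (FI) over 13
health-deficit variables. Each item is scored on [0, 1] with 0 the
healthiest state; the index is the mean of the per-item scores, so FI = 0
means no deficits and FI = 1 all deficits at their worst.

Two item kinds are supported:

* **Continuous** items are min–max rescaled, `(V_x − V_min)/(V_max − V_min)`,
  clamped to [0, 1]. When the *lower* end of the raw scale is the
  unhealthy one (grip strength, walking speed, activity), the score is
  reflected so 0 always means healthier. The `(V_min, V_max)` range is
  fixed from the cohort's observed values after excluding extreme
  outliers.
* **Binary** items are scored 0/1 at a cutpoint, with the direction flag
  deciding which side is the deficit (e.g. "54 or more steps to walk
  30 m" scores 1 on a 21–160 range).

**Outlier rule for the range.** "Extreme outliers" is formalised as a
quantile band, default (0.005, 0.995). The band endpoints are the order
statistics at positions `floor((n−1)·q)` — the nearest rank not exceeding
the requested quantile position — and only values strictly outside the
closed band are excluded. With this rule a single wild value (say 10000
among step counts of 21–160) is removed while the genuine minimum and
maximum survive; an interpolated quantile would clip the true minimum as
well, which is why the nearest-lower-rank convention was chosen.

**Missing items.** The index is the mean over non-missing items,
provided at least 80% of items (11 of 13) are scored; below that the
index is undefined and the record is excluded from downstream analyses.
This is the standard deficit-index convention; the threshold is
configurable (`IndexConfig.min_completeness`).

**Classification.** Frail is FI ≥ 0.25 by default. The boundary is
configurable (`ge`/`gt`) because the at-cutoff convention differs
between descriptive and analytic practice; everything downstream
respects the choice.

**Quintiles.** Gradient analyses bin FI into five equal-sized groups of
the *analysis subsample* (attendees with falls data at the outcome
visit), never of the full baseline cohort. Group sizes differ by at most
one, with the larger groups at the low end; ties are broken by stable
input order, so a permutation of the input permutes the labels
identically. Under heavy ties this size-balanced convention (rather than
value-based quantile boundaries) is what keeps the gradient tables
comparable across visit pairings.

## Empirical cutoff from 10-year mortality

`scan_mortality` walks a candidate grid (step 0.02) and records, at each
candidate c, the 10-year death proportion among participants with
FI ≥ c (optionally the frail-minus-non-frail difference; the at-or-above
proportion is the default because it is the more stable statistic at the
sparse upper tail). Candidates whose group has fewer than 10 members are
marked unstable and excluded from fitting.

`detect_slope_change` formalises "the beginning of a steeper slope" as a
continuous two-segment piecewise-linear least-squares fit with the
breakpoint restricted to the candidate grid: for every interior
candidate, the hinge model `y = b0 + b1·x + b2·max(x − c, 0)` is fitted
by least squares and the breakpoint minimising the residual sum of
squares wins, ties toward the smaller cutoff. A breakpoint counts as a
*distinct* changepoint only when the added slope is materially positive
and the upper slope is at least twice the lower slope (configurable);
otherwise the result is flagged so a globally linear curve is not
over-interpreted. On noiseless two-segment input the recovery is exact
for any grid knee.

A caveat worth knowing: the at-or-above curve is a *tail average* of the
individual risk curve, so when individual 10-year risk kinks at
FI = 0.25 the group curve begins steepening earlier and the detected
knee sits below 0.25. The changepoint finder recovers the knee of the
curve it is given; recovering an individual-level knee requires scanning
a curve sampled from that risk function directly (as the acceptance
checks do).

## Falls analyses

Falls in the previous 12 months define three categories: none, one
fall, recurrent (two or more). "Faller" means at least one fall in the
12 months before the classifying visit — no carry-forward of earlier
falls. Crossed with frailty status this yields the four fall–frailty
groups (faller/frail … non-faller/non-frail). Records with a missing
falls report are excluded *at analysis time* and counted, never dropped
at load time, because the shifting denominators between the full cohort
(1044/715/382) and the falls-valid subsets (914/711/382) are an easy
source of silent error.

Effect estimates:

* **2×2 odds ratios** use the cross-product with Woolf (log-scale) 95%
  intervals; a zero cell triggers the Haldane–Anscombe correction (0.5
  added to every cell), flagged on the estimate.
* **Logistic regression** (statsmodels maximum likelihood, Newton
  iterations, log-likelihood tolerance 1e−8) provides unadjusted and
  adjusted ORs with Wald intervals. For a single binary exposure the
  unadjusted logistic OR coincides with the cross-product OR, and the
  test suite enforces that equivalence to 1e−6. Adjustment covariates
  are 25(OH)D, BMI, smoking (three-level factor, never-smoker
  reference) and prior fracture; fits are complete-case with exclusion
  counts recorded. Non-convergence (typically separation in a small
  subgroup) raises a named error; the orchestrator skips such estimates
  rather than reporting unstable ones.
* **Per-0.01 increments**: the index is multiplied by 100 before
  fitting, so the exponentiated coefficient is directly the OR per 0.01
  of FI.

No multiple-testing correction is applied; p < 0.05 is read as nominal
significance. Percentages are reported to one decimal in tables while
all test comparisons use unrounded values.

## Synthetic cohorts

The generator emulates the statistical structure the analyses consume,
not any person-level data:

* **Latent-index-first.** Baseline latent frailty is Beta(2.80, 12.91).
  Continuous item scores are Beta(κt, κ(1−t)) with κ = 62 around the
  latent value t; the four binary items are Bernoulli(t). These
  constants are *calibration*, fitted once so the built index has
  baseline median 0.160, IQR ≈ 0.15 and frail prevalence 23.5%
  (`target_frail_prevalence`). The binary items make the built IQR
  slightly wider than the 0.14 target; that residual is accepted as the
  price of realistic mixed-kind items.
* **Outcomes are driven by the rebuilt index.** Falls, mortality and
  attendance all depend on the index recomputed from the observed
  deficits (after item missingness), i.e. on exactly the regressor the
  analysis uses. This is a deliberate choice: it makes the recovery
  experiments correctly specified, so estimator bias can be separated
  from measurement-error attenuation (which is not modelled).
* **Falls.** P(≥1 fall) and P(recurrent) are marginal logistic curves in
  100·FI with ORs 1.04 and 1.05 per 0.01 of index; a single shared
  uniform per woman realises both marginals simultaneously and keeps
  recurrent ⊆ any-fall. Intercepts (−1.663, −2.732) are calibrated to
  baseline incidences 28.4% / 14.7%. Recurrent counts are 2 plus a
  negative-binomial tail (n = 1, p = 0.6) — a modelling convenience,
  since only the 0/1/2/3+ categories are analysed.
* **Trajectories and attrition.** Latent frailty drifts by +0.0635 and
  +0.0763 per 5-year wave (with N(0, 0.015) noise), calibrated so the
  built median among attendees rises 0.16 → 0.21 → 0.27. Ten-year
  mortality is piecewise linear in baseline FI (base 0.18, slopes
  0.5 / 2.2, knee 0.25), split into two waves of equal conditional
  hazard. Attendance at each follow-up is logistic with slope −4 per
  unit FI, intercepts calibrated to expected attendee counts
  1044 → 715 → 382; attendance at the 10-year visit is nested within
  5-year attendance. Falls reports are missing completely at random at
  rates 12.5% / 0.6% / 0% per visit.
* **Covariates** are linear-in-FI with Gaussian noise (BMI slope +5.5,
  25(OH)D slope −30, fracture log-odds slope +2.05), matched to the
  frail/non-frail descriptive contrasts; smoking is an independent
  three-level multinomial. They are *not* confounders of the
  falls–frailty relation (falls depend on covariates only through FI),
  so adjusted and unadjusted estimates share the same estimand in the
  recovery experiments.

What passing recovery tests therefore show: the estimation code is
unbiased and correctly calibrated under the generator's assumptions
(logistic falls model, MCAR falls reports, no residual confounding,
no index measurement error in the outcome model). They do not show
robustness to recall bias, informative missingness, or confounding —
features of real cohorts the generator deliberately does not emulate.

## Problem sizes and numerical choices

Recovery experiments use 100 replicates at the cohort's own size
(n = 1044) for bias/coverage and 200 replicates for null rejection —
enough for Monte-Carlo error of ~2% on a coverage proportion while
keeping the full suite around a quarter of a minute. Changepoint
recovery uses 100 noisy curves (σ = 0.01 on the mortality scale).
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical config + seed yields bit-identical
cohort CSVs. Least-squares hinge fits use `numpy.linalg.lstsq`;
chi-square tests use `scipy.stats.chi2_contingency` without continuity
correction, with expected counts required positive.

## Known limitations

* The generator's deficit values are sampled around the latent index
  item-by-item; real deficits have richer cross-correlations (e.g.
  diabetes–BMI) that are not reproduced.
* Only binary 10-year mortality is modelled — no survival times, no
  competing-risk structure.
* The 40-item comparison index is not constructed; `compare_indices`
  only correlates two supplied index vectors.
* Published-count reproductions are exact by construction where the
  source tables are internally consistent; two small source-side
  inconsistencies (a 12.2% vs 12.1% cell, a 625 vs 623 reconstructed
  denominator) are surfaced by the tests rather than patched.
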