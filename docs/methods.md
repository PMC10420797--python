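# Methods and design notes

This note records the scientific conventions the package implements, the
choices made where the field leaves room, and what the synthetic-data
tests do and do not demonstrate.

## Clock-time and MCTQ conventions

All clock times are decimal hours on an unrolled 0–48 h axis; onsets
after midnight are encoded as 24 + h, and wake times given on the 0–24
dial are unrolled by adding 24 h whenever wake ≤ onset. Mid-sleep points
are reported modulo 24. This removes every midnight-crossing ambiguity
and makes social jetlag a plain difference of unrolled mid-sleeps, which
may be negative for phase-advanced sleepers (an `sjl_absolute` switch
reports |SJL| for categorical uses such as the SJL ≥ 1 h flag).

Three conventions are configurable because the literature prints them
inconsistently:

- **Sleep efficiency.** The standard definition SlE = SlD/TiB × 100 is
  the default; the transposed form TiB/SlD × 100 that sometimes appears
  in print yields values above 100 and is available as
  `sle_formula="as_printed"` for exact replication of such workflows.
- **Chronotype correction.** MSF_sc = MSF − 0.5 (SlD_F − SlD) is applied
  only when free-day sleep exceeds work-day sleep and no alarm is used on
  free days (the original MCTQ rule); `msfsc_correction="unconditional"`
  applies it always.
- **SJL sign.** Signed by default; see above.

## PSQI and ZSDS

PSQI components follow the published scoring sheet (latency minutes
banded at 15/30/60; duration at 7/6/5 h; habitual efficiency at
85/75/65%; disturbance sum at 0/9/18; daytime dysfunction as the banded
sum of two items). The global score is the component sum (0–21) and > 5
flags poor sleep. The ZSDS raw sum (20–80) uses the standard
reverse-keyed item set {2, 5, 6, 11, 12, 14, 16, 17, 18, 20}
(configurable); the index is raw × 1.25, stored at full precision, with
integer presentation rounding half away from zero, and severity bands
≤ 50 / 51–59 / 60–69 / ≥ 70.

## Anthropometrics

BMI percentiles come from an LMS reference via
z = ((BMI/M)^L − 1)/(L·S) and the normal CDF. The packaged reference is
**synthetic** (smooth curves in the range of published adolescent
charts) so the pipeline runs self-contained; any official chart can be
supplied as CSV (sex, age_months, L, M, S). Growth references end at 19
years while young-adult cohorts extend to 25; by default ages above the
table ceiling use the oldest column (disable with
`adult_uses_oldest=False` to make that an error); ages below the floor
always raise — no extrapolation. Weight-status categories use the
5th/85th/95th percentile cuts; central adiposity is WHtR ≥ 0.5.

## FFQ exposure

The eight frequency categories map to occasions/day by interval midpoints
(month = 30.44 days; the open top category ">4/day" is floored at 5).
Daily intake per product is rate × servings × serving mass × content;
dinner intake weights each product by its dinner percentage. Zero totals
store missing (never −∞) logs and are excluded from log-scale models
with a logged count. The default product table is illustrative: content
values in the food-melatonin literature vary by orders of magnitude
between studies and cultivars, so any substantive analysis must supply
its own audited table (CSV/JSON, ng/g or ng/serving).

Tertiles cut at the order statistics of ranks ⌈n/3⌉ and ⌈2n/3⌉; boundary
ties fall to the lower tertile (intervals are [low, high)); fully tied
input is flagged degenerate rather than split arbitrarily.

## Association analyses

Stepwise selection uses the SPSS-style defaults (entry p = 0.05, removal
p = 0.10, both configurable) with t-test entry for OLS and
likelihood-ratio entry for logistic models; predictors reaching
VIF ≥ 5 are excluded outright. Standardized β is B·sd(x)/sd(y);
cumulative R² and ΔR² are reported in entry order, and Bonferroni
correction multiplies by the final model size by default. City and study
mode enter as integer codes by default (`strict_paper=True`) to mirror
the common questionnaire-epidemiology workflow; `strict_paper=False`
dummy-codes them properly. Logistic models report Wald 95% CIs, the
omnibus LR χ² against the null, and the Hosmer–Lemeshow statistic on ten
fitted-risk groups with g − 2 df (undefined — reported as NaN — when the
final model yields fewer than three distinct risk levels). Quasi-complete
separation drops the offending predictor with a flag; no penalized
fallback, since plain odds ratios are the reporting target.

ANCOVA tests the tertile factor by extra sum of squares after the
covariates (equivalent to Type III here, the factor being the only
non-covariate term); η² is classical (SS_factor/SS_total), not partial.
Adjusted means are model predictions at the grand covariate means;
reported SDs are raw within-group SDs. Post hoc pairwise comparisons of
adjusted means are unadjusted by default (mapped to the
<0.05/<0.01/<0.001/<0.0001 tiers), with a Bonferroni option.

## Synthetic cohort generator

The generator's defaults encode the study conditions it emulates:
n = 1277; 72.8% female; city shares 21.9/20.6/57.5%; 27.3% remote study;
FMT1_day ~ N(7.01, 1.13); FMT1_dinner mean 5.68, SD 1.50 with day–dinner
correlation 0.8; outcome marginals and standardized coefficients
(e.g. depression index: sex −0.232, daily exposure −0.111; chronotype:
−0.088; social jetlag: −0.068) with residual variance set to
1 − Σβ² (predictors are independent by construction, and infeasible
coefficient sets are rejected at configuration time).

Specific emulation choices:

- **Age** is a two-component uniform mixture, U(16, 16.7) with
  probability 0.5711 and U(24.3, 25), solved for mean 19.91 and SD 4.11.
  No single smooth law on 16–25 attains that SD, and the implied
  skew/kurtosis of such data are not jointly attainable either; only the
  first two moments are targeted.
- **Dinner share.** ln FMT_dinner − ln FMT_day = ln(share), with share
  following a Beta law whose log-moments are solved exactly from the
  configured dinner mean/SD via digamma/trigamma identities, coupled to
  FMT1_day through a Gaussian copula whose correlation is calibrated by
  Gauss–Hermite quadrature. The dinner *mean* is exact by construction;
  the dinner *SD* and the day–dinner correlation are approximate (the
  copula acts on a nonlinear transform), accurate to about 1–2%, and the
  tests assert them at that tolerance rather than at Monte-Carlo width.
- **Agec** = 1/exp(age) is kept at full precision (~10⁻¹¹–10⁻⁷ on this
  age range). Model inputs are never rescaled; standardized coefficients
  are scale-invariant, and reports may apply a display multiplier only.
- **Instrument floors/ceilings.** Latent Gaussian outcomes are clipped
  into each instrument's representable range before item construction
  (PSQI 0–21, ZSDS index 25–100, and jointly feasible sleep-timing
  windows), and the clipped values are stored as the recovery targets.
  Configured effects are therefore defined on the latent linear-Gaussian
  system; fitting the published model structures to generated cohorts
  recovers them without selection or censoring bias, which is what the
  effect-recovery tests check. Scored (item-level) variables additionally
  carry instrument quantization and floor effects, exactly as real
  questionnaire data do.
- **Inverse item construction** is deterministic: sleep schedules on a
  5-minute grid with equal work/free durations (so the chronotype
  correction is inactive and targets invert exactly); PSQI component
  targets distributed greedily and realized by canonical item patterns;
  ZSDS keyed scores distributed greedily then un-keyed; FFQ intake split
  across three default products proportional to their per-serving
  content, with the shared frequency × servings choice taken log-nearest
  on the 42-point achievable grid (largest adjacent log-gap ln 2, so
  recovery is within half that, ≈ 0.347 nats) and dinner percentages
  chosen greedily in quarter steps (share recovered within 0.125).

What passing these tests shows: the scoring code inverts correctly, the
statistical machinery is calibrated, and effects of the configured
magnitude are recoverable at the configured sample size. What it does
not show: anything about real dietary measurement error, recall bias,
item non-response, the joint distribution of real instruments beyond the
configured marginals and coefficients, or causal direction.

## Problem sizes and numerical choices

Simulation-based tests use 200 replicates of n = 1277 for effect
recovery, 500 replicates for null calibration (99% binomial bands
around the 5% nominal level), 1000 draws for round trips and n = 10⁵ for
moment checks — sizes chosen so Monte-Carlo error is well below the
tolerances being asserted. Oracle-equivalence checks (η², F, ΔR², odds
ratios against explicit projection/cross-product computations) are
asserted at 10⁻⁸ on fixtures of ≤ 20 rows. Ties, degenerate tertiles,
perfect collinearity, separation and empty stepwise models are all
handled by explicit flags or errors rather than silent fallbacks, as
described above.

## Known limitations

- The default product table and the synthetic LMS reference are
  placeholders for audited inputs; absolute exposure levels and BMI
  percentiles computed from them carry no substantive meaning.
- Integer-coded city/mode covariates (the default, for workflow
  fidelity) impose a linearity assumption a dummy coding would not.
- The generator draws outcome residuals independently across outcomes;
  cross-outcome correlations (e.g. between sleep quality and depression)
  are not emulated.
- Printed summary statistics of some transformed variables in the
  emulated study (the Agec row, the continuous "WHtRc" row and the
  capped sleep-efficiency row) are mutually inconsistent with their
  stated definitions; the transforms are implemented as defined and the
  generator targets the raw-variable marginals instead.
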