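# Methods

`somnocohort` reimplements, as a tested pipeline, the analysis of a wearable
digital-phenotyping cohort study: consumer-tracker sleep logs and PSQI
questionnaires from several hundred volunteers, merged with cardiovascular
risk markers and leukocyte telomere length (LTL), and analysed with a battery
of covariate-adjusted Gaussian linear models. This note records the model
choices, defaults, and the points where the underlying conventions were
genuinely open.

## Wearable ingest and quality control

Sleep arrives as per-volunteer JSON arrays of sessions (`startTime`,
`endTime`, `minutesAsleep`, `timeInBed`, `awakeningsCount`); activity as
per-day records (`date`, `hrCoverageHours`, `steps`). The dialect is a
minimal, documented subset of the Fitbit Web API sleep payload, not a clone
of any particular API version. All timestamps are naive local clock times at
minute resolution; the design assumes a single-timezone study and performs
no timezone arithmetic.

Sleep efficiency is always recomputed as `100 * minutes_asleep /
minutes_in_bed`, never trusted from the file, so the SE definition is
single-sourced. Sessions whose end does not follow their start are skipped
with a counted, reported reason; other invariant violations (sleep minutes
exceeding bed minutes, bed minutes exceeding the session span plus one
minute of rounding slack) raise record-level validation errors.

A tracker day is *data-complete* when heart-rate coverage is at least 20 h
(inclusive) and the step count is nonzero; a volunteer is included with at
least three complete days. Both thresholds are arguments with those
defaults. A night is retained iff its **start** calendar day is complete —
gating on the end day or both days would also be defensible; the start day
was chosen because sessions are keyed by start time throughout. An optional
percentile filter on mean daily steps ("extreme activity" removal) exists
but is off by default, because no quantitative definition of extreme is
canonical.

## Sleep metrics

A session belongs to night *D* iff it starts in the half-open window
[20:00 of *D*, 08:00 of *D*+1); the half-open right edge prevents a session
starting exactly at 08:00 from counting toward either night. Sessions
starting in [08:00, 20:00) are naps: excluded from every metric, reported by
count. Nightly TST is the sum of assigned sessions' sleep minutes; nightly
SE the *unweighted* mean of their efficiencies (time-weighting would be the
alternative; the unweighted form mirrors "average SE of sleep sessions");
nightly awakenings the sum of wake counts. Volunteer metrics are plain means
over retained nights, TST converted to hours.

Sleep hour and wake hour are means of the start and end clock times of
window-assigned sessions whose **bed interval** lasts at least 3 h
(configurable to sleep minutes). The wake-hour average uses the same
≥3 h-filtered session set as the sleep hour — applying the filter to one but
not the other would make the two hours incomparable. Because these clock
times span midnight, a naive mean is ill-defined; times are mapped to minute
offsets past the 20:00 window origin (all offsets lie in [0, 1440)),
averaged arithmetically, and mapped back, so 23:00 and 01:00 average to
00:00. A brute-force minute-enumeration oracle checks this on a 10-minute
grid across the window.

## PSQI scoring

All seven components of the 19-item instrument are scored (the five
bed-partner items are not part of the score). Component 3 (duration) uses
>7 h → 0, (6, 7] → 1, [5, 6] → 2, <5 → 3; component 4 (habitual SE =
self-reported sleep hours over bed-to-rise clock time, wrapping midnight)
uses >85% → 0, [75, 85] → 1, [65, 75) → 2, <65 → 3. Printed band labels
("6 to 7 hours", "75–84%") overlap at their edges in most renderings of the
instrument; the edges above follow the original instrument convention, sit
in one place in the code, and the tests pin them. Component 5 sums the nine
disturbance items 5b–5j and bands the total 0 / 1–9 / 10–18 / 19–27;
components 2 and 7 band their two-item sums 0 / 1–2 / 3–4 / 5–6. Question
5b's frequency code (0 = not in the past month … 3 = three or more times a
week) is itself the score and doubles as the self-reported counterpart of
tracker-detected awakenings. Missing items raise an error naming the item;
no imputation.

## Association battery

All models are Gaussian GLMs (ordinary least squares) via patsy formulas:
marker models `Marker ~ Age + Gender + Ethnicity + DailySteps + TST` (and SE,
and TST+SE), demographic and socioeconomic models
`TST ~ Age + Gender + Ethnicity (+ Factor)`, telomere models
`LTL ~ Age + Gender + Ethnicity + BMI + TST` plus TST×age and TST×gender
interactions and the sleep-stratum contrasts. Reference levels are fixed:
Female; Chinese; Public-housing; Others (education); Manual-labor; "No" for
alcohol/caffeine; Ex-smoker; Never/hardly. Sleep strata: insufficient
(<5 h) vs adequate (>7 h), the 5–7 h middle excluded from the contrast; the
three-level variant splits adequate (>7, ≤9] from long (>9), adequate being
the reference.

95% intervals are Wald, `beta ± 1.96·SE`, so they differ in the third
decimal from t-based intervals at these sample sizes. Incomplete rows are
dropped listwise per model (before design construction, so a factor level
confined to incomplete rows does not linger as an all-zero column) and the
per-fit n is reported. Rank-deficient designs raise an error naming the
collinear columns. **No multiple-testing correction is applied anywhere**:
the battery reports raw p-values, which is faithful to the analysis style it
reimplements but means a run over ~30 models × ~8 terms is expected to flag
~5% of null terms; treat single uncorrected p-values accordingly.

Correlation conventions: Spearman for continuous-vs-ordinal (questionnaire)
pairs, Pearson for continuous pairs, both two-sided, pairwise-complete.
Group contrasts use two-sided Student's t (unpaired or paired) and the
chi-squared test for two categorical vectors.

## Telomere length

qPCR T/S follows the relative-quantification design: telomere (T) and
single-copy 36B4 (S) reactions on separate plates in identical positions,
samples in triplicate, a reference DNA diluted threefold
(109.0 → 36.3 → 12.1 → 4.0 → 1.3 ng/µL) giving each plate a standard curve
`Cq = slope·log10(conc) + intercept` (efficiency `10^(−1/slope) − 1`).
Triplicate outliers: the well farthest from the triplicate median is dropped
when it deviates by more than 0.5 cycles; if the survivors' concentration CV
still exceeds 15% the sample is flagged for repeat. Both thresholds are
arguments; the 0.5-cycle rule is common qPCR practice rather than a unique
convention.

Inter-plate normalization divides every concentration by the plate's
control-sample mean. This expresses T/S relative to the control DNA's own
T/S — the usual relative-quantification convention — and makes the final
ratios exactly invariant to rescaling any single plate, a property the test
suite asserts. An alternative anchor (`reference="grand_mean"`), keeping
concentrations on the ng/µL scale by scaling each plate to the control's
grand mean across plates, is provided but is only approximately
scale-invariant, since the grand mean itself moves with the rescaled plate.

Batch effects (two qPCR extraction batches; multiple WGS sequencing runs)
are removed by linear regression on batch indicators: adjusted value =
residual + grand mean, which maps every batch mean onto the grand mean
exactly while preserving within-batch variation. T and S concentrations are
adjusted separately before the final ratio; WGS LTL estimates (consumed as
base-pair values from an external read-ratio estimator, not recomputed) are
adjusted the same way for sequencing run. T/S ratios are deliberately not
rescaled to base pairs.

## Synthetic cohort

The generator's defaults are the study conditions: 482 volunteers, ~54%
female, ethnicity 91.1/3.5/3.3/2.1% (Chinese/Indian/Malay/Others), ages
21–69; 3–11 tracked nights per volunteer (3 + Poisson(1), mean ≈4); nightly
sleep around a volunteer-level mean of 388 min (between-volunteer SD 55 min,
nightly SD 45 min) with planted effects −16 min (male), +19 (alcohol), −41
(Malay), +32 (Indian), −27 (manual work), +15 (private residence); SE
~Normal(92.584, 3.060) at the volunteer level; awakenings Poisson(2) per
night. The planted-effect expectation is subtracted from the baseline so the
cohort mean stays at 388 min by construction. Nights start around 23:15,
15% are split into two sessions, naps are injected on 10% of days, and 12%
of tracker days are incomplete (low coverage or zero steps), driving the QC
path. LTL is drawn in bp with age-group effects −259 (40–60) and −432
(60–80) versus 20–40 and a sleep-stratum effect of 356 bp (adequate vs
insufficient, interpolated across the excluded 5–7 h middle so the contrast
equals the planted magnitude exactly); qPCR T/S is a linear map of bp
(7.1e-4 T/S per bp around 1.0). Marker–sleep slopes default to zero so the
marker battery is null-calibrated out of the box.

Self-reported sleep = true TST + 6 min bias + Normal(0, 180 min) recall
noise, rounded to the half hour and clipped near-symmetrically about the
cohort mean (so truncation does not distort the planted bias). The 180-min
noise SD was chosen so the volunteer-level rank correlation between
self-report and tracker lands in the ≈0.3 regime such studies observe; it is
a recall-noise abstraction, not a model of systematic reporting styles.

All randomness flows from one seed through per-volunteer `SeedSequence`
substreams, so bundles are byte-identical across runs and adding volunteers
never perturbs existing ones. Ground truth records per-volunteer true
metrics **over QC-retained nights** plus every planted coefficient.

What the generator does *not* emulate: intra-night sleep architecture
(stages, HR dynamics), seasonal or weekday structure, correlated missingness
(incomplete days are independent of sleep), measurement error in the tracker
itself (sessions are taken at face value), and realistic covariance between
markers. Passing tests therefore demonstrate the pipeline's arithmetic,
filtering and inferential calibration under the planted model — not the
device-level validity of wearable sleep staging.

## Numerical and testing choices

- Monte-Carlo scales: type-I calibration uses 200 null cohorts of n = 500
  (≈4,200 null terms); CI-coverage uses 500 cohorts of n = 482. Both run on
  the fast table-level generator; the raw-stream path is exercised by the
  exact noiseless-limit identity (n = 100) and the end-to-end truth-matching
  test on a default bundle.
- Wald (z) intervals with an estimated Gaussian scale cover slightly below
  95% in finite samples (≈94.9% at these n); the coverage acceptance band is
  93–97%.
- Clock means are rounded to the nearest minute; ties in the triplicate
  outlier rule resolve to the first farthest well (`argmax`).
- Degenerate inputs fail loudly: empty time lists, constant correlation
  vectors, single-concentration standard curves, groups of n < 2, unseen
  factor levels, missing PSQI items. A single batch is the one deliberate
  soft case — batch adjustment warns and returns the input unchanged.
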