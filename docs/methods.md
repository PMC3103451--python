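# Methods

`refluxpred` reproduces, end to end, the statistical analysis of an 8-week
course of a proton pump inhibitor (PPI) in gastro-oesophageal reflux
disease (GORD), as performed on daily patient-reported ReQuest scores in a
large pragmatic trial setting (intention-to-treat n = 1888).  The trial's
raw data are not public, so the package pairs the analysis code with a
synthetic cohort generator calibrated to the published cohort-level
figures.  This note records the models, the defaults and why, and what a
green test does and does not establish.

## Instruments and scoring (`scores`)

The short-form ReQuest questionnaire covers seven symptom dimensions, each
with a 100 mm intensity VAS and (except general well-being) a 0–6
frequency Likert item.  Dimensions group into the GI sub-scale (acid,
upper abdominal, lower abdominal, nausea; range 0–30.77) and the WSO
sub-scale (well-being, sleep, other; range 0–15.51); the total ranges
0–46.28.  The proprietary item-to-score algorithm is not public; the
package uses a documented stand-in,

    dimension score = weight_d × (intensity/100) × (frequency/6),

intensity-only for well-being, with per-dimension weights defaulting to an
equal split of the sub-scale maxima.  This preserves the published ranges,
monotonicity, and the sub-scale structure — the only properties downstream
stages rely on.  The simulator emits dimension-level scores directly and
does not depend on the stand-in.

HADS is scored exactly as published: two 7-item sub-scales (anxiety,
depression), items 0–3, bands normal 0–7, suggestive 8–10, probable ≥ 11.
The default item-to-subscale layout alternates items (odd → anxiety) and
is configurable.  GERDyzer's ten 0–100 VAS dimensions are aggregated as
their mean, keeping the 0–100 interpretation (the source reports only
"scores"; sum vs mean is unstated).

## Responder rule (`responder`)

A patient responds if the daily GI score is **below 1.6 on 3 consecutive
calendar days**, the run lying entirely within treatment days (day ≥ 1;
day 0 is pre-treatment) and ending on or before the horizon (day 28 =
Week 4, day 56 = Week 8).  1.6 is the 95% upper confidence limit of
healthy-subject scores.  Choices where the source is silent:

* strict inequality (`< 1.6`), reading "below" literally; configurable;
* a missing day breaks a run (conservative); a skip-missing variant is
  available;
* "response at Week k" means the run completed on or before that day, not
  symptom state at the visit — consistent with cumulative response rates
  rising from Week 4 to Week 8;
* patients are classified on their available data; no imputation of
  dropouts.

## Dual prediction-level search (`prediction`)

For day 0 (baseline) and treatment days 1–10, and each score kind (total,
GI, WSO), levels are swept in steps of 0.01 from 0 to the score maximum.
At level L, scores ≤ L predict response and scores > L predict
non-response; the prediction rates are the corresponding positive/negative
predictive values against the Week-8 classification.  Per day the search
keeps the level maximising each rate; the best day minimises the
indeterminate zone width U − L (ties → earliest day).  Numerical and
degeneracy choices:

* levels are integer multiples of the step (no floating-point drift);
  `score ≤ level` is tested with a 1e-9 tolerance;
* without a support constraint the "highest rate" is degenerate (a single
  patient attains rate 1), so both sides require a minimum group size,
  default 30, configurable and reported;
* tie-breaks: maximal rate first, then maximal group size (coverage), then
  the boundary-hugging level — smallest for L, largest for U.  Within a
  (rate, coverage) tie the predicted groups are identical; the final rule
  only fixes where inside an empty score gap the levels sit, and keeps
  L ≤ U whenever the groups are orderable (under perfect separation a
  pure "largest L / smallest U" rule would cross the levels and falsely
  flag the day);
* days where no level meets the group minimum, or where L > U, are
  flagged inadmissible, never silently dropped;
* patients missing a day's score are excluded from that day's
  denominators;
* rates are reported as percentages rounded to one decimal.

No ROC/AUC or cross-validation machinery is added: the procedure is an
in-sample level search and is reproduced as such.

## Logistic factor screening (`regression`)

Univariate screening fits one logistic model per factor (ERD/NERD, HADS
total and sub-scores, IBS, BMI, gender, geography, H. pylori, age, and
oesophagitis grade within the erosive subgroup only) with Week-8 response
as outcome; a global multivariate model (ERD/NERD by presence, HADS as
total only) adjusts for confounding.  Implementation choices:

* maximum likelihood via Newton iterations (statsmodels `Logit`),
  log-likelihood tolerance 1e-8; Wald standard errors;
* each factor gets a likelihood-ratio p-value (null vs factor model) —
  the single per-factor p the screening table reports; per-level Wald p's
  accompany it;
* separation is flagged (`separation=True`, `converged=False`), never
  returned as a silent estimate;
* complete-case handling: H. pylori "missing" is dropped, "intermediate"
  kept as its own category; IBS "unknown" kept as a genuine answer;
  dropped-row counts are reported;
* BMI and age enter untransformed (per-unit odds ratios);
* no multiple-testing adjustment — the screen is explorative, as in the
  source analysis.

## Concordance and quality of life (`outcomes`)

Satisfaction ('very'/'fairly'/'not satisfied') and investigator assessment
('well'/'fairly'/'not controlled') are cross-tabulated against the
responder classification at the same visit.  The headline discordance
measures are the non-responder share of the top category and the share of
responders in the worst category.  GERDyzer falls (baseline to visit) are
compared between responder groups with an unpaired Welch test; the source
names no test, only p-values.

## Synthetic cohort (`cohort_sim`)

The generator states a world consistent with the published cohort-level
figures and keeps it fixed:

* **Covariates.**  Categorical marginals equal the published baseline
  tables (gender 51.8% female; NERD 36.8%, grades A–D 36.0/20.2/5.1/1.2%,
  0.7% missing; H. pylori 36.4/56.7/5.2/1.7%; six geographies; smoking
  62.4/19.1/18.5%).  Age ~ N(47.0, 14.3²), BMI ~ N(26.4, 4.8²), clipped to
  plausible ranges.  The IBS marginal is not published; {yes 0.25, no
  0.65, unknown 0.10} reflects the elevated IBS overlap reported in GORD
  populations.  NERD, IBS and baseline anxiety are more prevalent in
  women (P(NERD|F) = 0.48, P(IBS|F) = 0.33, anxiety +1.5 points), the male
  probabilities derived to preserve the overall marginals — this is what
  makes the univariate gender effect mostly a confound, as the published
  multivariate result requires.
* **Latent response.**  Bernoulli with logit = 0.82 + 0.55·ERD +
  0.18·male + 0.25·(BMI−26.4)/4.8 − 0.048·(HADS total − 14) − 0.45·IBS −
  0.10·IBS-unknown + geography contrasts (South Africa +0.60, Asia −0.50,
  Australia −0.45 vs Western Europe); age, smoking and H. pylori have
  null effects, matching the published non-significant factors.
* **Daily scores.**  GI(t) = a + (b − a)·e^(−t/τ) + ε, truncated to
  [0, 30.77]: baseline severity b = 1.8 + Gamma(1.8, 3.2); asymptote
  a = 0.5 (responders) / 3.5 (non-responders); τ log-normal with median
  8.3 days (σ = 0.45) for responders and 45 days (σ = 0.30) for
  non-responders; daily noise sd 0.8.  WSO is a patient-specific fraction
  (N(0.36, 0.10²)) of GI plus noise; total = GI + WSO.  Post-baseline days
  are missing completely at random with probability 0.03; day 0 is always
  observed.  Exponential decay toward a class asymptote is the simplest
  mechanism giving covariate-linked time-to-response; the trial reports
  no within-patient autocorrelation or dropout pattern, so MCAR and
  independent daily noise are pragmatic defaults, not inferences.
* **Calibration.**  The free parameters (intercept, τ medians, the
  gender-linked prevalences, β_male) were tuned once by grid search over
  seeded cohorts until the classifier reproduced the published rates —
  Week 4 58.9%, Week 8 71.2%, ERD 75.5%, male 74.9%, female 67.8% — to
  within ±1pp on the multi-seed mean, then frozen as the packaged
  defaults.  They were not revisited afterwards.  Single-cohort values
  scatter around these means with a binomial standard error of ≈ 1pp.
* **Assessments.**  Satisfaction and investigator categories are drawn
  from misclassification matrices conditioned on the classifier outcome
  at the visit, derived from the published Week-8 discordance counts
  (155 of 1110 'very satisfied' are non-responders → 14%; 0.8% of
  responders 'not satisfied'; 310 of 1450 'well-controlled' are
  non-responders).  Week-4 visits reuse the Week-8 matrices (no Week-4
  counts are published).  HADS follow-up declines linearly with class:
  responders' anxiety falls into the normal band (< 7) by Week 8,
  non-responders' stays above it; depression stays in the normal band
  throughout.  GERDyzer starts higher and falls less in non-responders.

**What the simulator does not emulate:** real score autocorrelation,
informative dropout, item-level instrument responses, centre effects,
adverse events, or any geographic biology — geography contrasts only
reproduce the published ordering qualitatively.  A green calibration test
establishes that the pipeline recovers the stated world's parameters, not
that the world equals the trial.

## Pipeline (`cli`)

`refluxpred run` executes simulate → respond → predict → regress →
outcomes, writing CSV/JSON artefacts plus a manifest with the seed and a
hash of the effective configuration.  Supplying pre-built cohort CSVs
(`--cohort`) bypasses simulation and yields byte-identical downstream
outputs.  Everything is deterministic given the seed.

## Known limitations

* The ReQuest item-to-score rule is a stand-in; only range and
  monotonicity are faithful.
* The dual-level search reproduces published prediction rates only as
  arithmetic on the printed group counts; the synthetic cohort's own
  optimal levels differ from the printed ones because the latent classes
  separate more cleanly than real patients do.
* The misclassification matrices are identified only up to the published
  marginal discordances; the full 3×2 tables are under-determined and the
  remaining cells are chosen to be plausible.
* Type-I error of the Wald test in the screening configuration measures
  slightly above nominal (≈ 0.066 at n = 1888 over 500 replicates),
  consistent with the large-sample approximation, and is asserted within
  [0.03, 0.07].
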