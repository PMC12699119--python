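# Methods

This note documents the statistical models implemented in `ppidqol`, the
design of the synthetic-data generator, the numerical conventions, and the
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Instrument and score

The packaged final instrument (`ppid-final-24`) has 24 Likert-type items in
seven domains. Every item maps its ordered options to non-negative scores
starting at 0; higher is worse. Positively phrased items ("My horse looks
healthy") carry reversed scores, so polarity is metadata only. Two kinds of
escape option exist:

* *"I have not been able to observe this"* scores the item midpoint
  (e.g., 1.5 on a 0–3 item), so an unobservable behaviour neither inflates
  nor deflates the total.
* *"My horse does not receive any meds/suppl."* on the medication-ingestion
  item scores 0. No published convention exists for this option; 0 is the
  natural choice (no medication burden means no negative impact on QoL) and
  the value is configurable in the instrument file.

Domain weights are the median owner importance ratings (1–5) from PPID-horse
owners: demeanour 5, appearance 4, condition 4, health 5, appetite 5,
ingestion 5, management 5. These weights are applied to all horses,
including non-PPID controls, matching the design intent of a PPID-specific
tool. The normalized score is the weighted item sum over the weighted
maximum (383 for the packaged instrument); it is invariant under rescaling
all weights by a common positive factor, which is why the `DomainWeights`
container accepts any positive rationals even though importance-derived
weights are integers in 1..5.

Scores are computed in double precision; all packaged option scores and
weights are dyadic rationals, so sums are exact and only the final division
rounds. Reported tables round to 4 decimals.

The scorer refuses incomplete records (development of the instrument
excluded incomplete survey responses); an explicit `impute_midpoint=True`
flag substitutes the per-item midpoint instead and is labelled an extension.

Median importance ratings use the midpoint convention for even n, rounded
half-up to an integer weight (weights are integer importance levels; a
[3, 5] vector yields 4, a [4, 5] vector yields 5).

## Survey bank and refinement arithmetic

The packaged survey bank (`ppid-survey-37`) holds the 37 items fielded in
the development survey. The 24 retained wordings are the final tool's; the
13 removed or merged wordings come from the published refinement account,
with response scales reconstructed to match the reported chi-squared degrees
of freedom (a two-group table with K categories has df = K − 1). The
reconstruction is marked in the data file. The published account removes 7
items by chi-squared, merges one demeanour pair statistically, prunes 5
items by item-total correlation, and merges one medication pair editorially
— arithmetic that closes to 24 only if the editorial medication merge is
packaged as a single survey item under its combined wording, which is what
this bank does (37 − 7 − 5 − 1 = 24). The initial interview-derived 42-item
bank survives only as a metadata stub (`load_bank_stub()`): the five items
removed during piloting were never published.

## Refinement procedure

Stages run in the order chi-squared filter → redundancy merge → item-total
pruning (configurable; this order follows the narrative of the development
account). Thresholds p < 0.05, r > 0.60, r < 0.30 and the adequacy bound
α > 0.70 are configuration defaults, not constants.

* **Stage 1** tests each item's response-category × group table with the
  Pearson chi-squared test of independence (no continuity correction, no
  category collapsing; expected counts below 5 raise a warning). Degenerate
  single-category tables are flagged for manual review and retained.
* **Stage 2** (PPID rows only) repeatedly merges the same-domain pair with
  the highest inter-item Pearson r above the threshold. Merged responses
  default to the element-wise maximum of the pair — the worst-case reading
  of two near-identical questions; `mean` and `first` are selectable. The
  published process merged question *wordings* and describes no score
  arithmetic, so this is a package convention, chosen for determinism and
  conservatism.
* **Stage 3** computes corrected item-total correlations (each item against
  the sum of the others); among items below the threshold it removes the one
  whose removal most increases Cronbach's α, recomputes, and stops when no
  candidate removal increases α. Ties on the α gain break toward the lowest
  item-total r, then input order. By construction the α trajectory is
  non-decreasing during pruning.

Cronbach's α = k/(k−1) · (1 − Σ var_i / var_total) with unbiased (n−1)
variances, computed on raw unweighted scores of the PPID group only. The
report records every action with its statistic, the α trajectory, terminal
dispositions for all input items, and warnings (e.g., an emptied domain).

## Reliability and validity

ICCs are two-way single-measure forms from the subjects × raters ANOVA mean
squares: consistency (MS_R − MS_E)/(MS_R + (k−1)MS_E), used for
within-observer repeat occasions, and absolute agreement, which adds
k(MS_C − MS_E)/n to the denominator and so penalizes systematic rater
offsets, used between observers. The development study did not state one-
versus two-way; two-way is chosen because it makes that distinction
meaningful. Confidence intervals use the exact-F construction for the
consistency form and the McGraw–Wong approximation for absolute agreement;
qualitative bands are <0.50 poor, 0.50–0.75 moderate, 0.75–0.90 good,
>0.90 excellent. Estimates are translation invariant, and the consistency
form is additionally invariant under per-rater constant offsets (tested).

Face validity is the Spearman rank correlation (average ranks for ties,
two-sided p) between the owner's direct 1–5 QoL rating and the computed
score. Ordinal association between two groups' importance-rating
distributions uses Stuart's tau-c, suited to rectangular (here 2 × m)
tables, with its asymptotic p-value; a brute-force O(n²) concordance count
serves as the test oracle.

## Association models

The dependent variable is sqrt(HRQoL): the score is bounded and
right-skewed, and the square root improves residual normality (checked by
Shapiro–Wilk). Models are ordinary least squares with Type III sums of
squares under sum-to-zero contrasts; each term's F is tested against the
residual mean square, and Type III makes the tests invariant to term order
(tested). Two presets are packaged: `all-horses` (fixed: PPID, chronic
comorbidity; categorical: breed, sex, body condition; covariate: age) and
`ppid-only` (fixed: treatment, chronic; categorical: breed, sex, body
condition; covariates: age, years diagnosed). Interactions are restricted
to factor × covariate pairs.

Two deliberate deviations from the original analysis software's behaviour:

* Background factors declared "random" there are modelled here as fixed
  categorical effects with residual-denominator F tests — consistent with
  the residual-style denominator dfs reported in that analysis — rather
  than via expected-mean-squares quasi-F denominators.
* Covariates are centered before interactions are formed, so a factor's
  Type III main effect is evaluated at the covariate mean rather than at
  covariate 0 (an age of zero lies far outside any equine cohort and would
  make the main-effect tests uninterpretable and underpowered).

Homoscedasticity, assessed visually in the original workflow, is
operationalized as a Breusch–Pagan flag. Rows missing any model variable
are dropped listwise and counted. Rank-deficient designs raise an error
naming the aliased columns.

## Synthetic cohort generator

The generator emulates the structure the analyses assume; it is not a
reproduction of the unavailable field data. Each horse carries a latent
severity θ = β₀ + β_PPID·PPID + β_chronic·chronic + β_age·z(age) + ε,
ε ~ N(0,1), with ages drawn per group (defaults 24.34 ± 6.60 years for 343
PPID horses, 19.84 ± 5.16 for 269 controls) and z standardized against the
theoretical pooled mixture. Item responses come from an underlying draw
u_i = a_i·θ + ε_i cut at fixed thresholds — a graded-response mechanism that
makes every response distribution stochastically increasing in θ by
construction. Thresholds are set so an average control horse reproduces a
realistic skew toward the favourable end of each scale. The unobservable
option is emitted with a small θ-independent probability (unobservability
is a property of housing, not severity); the no-medication option is more
frequent among controls.

Planted structure: designated *non-discriminating* items ignore θ entirely;
*noise* items carry a group mean shift but zero loading (so they pass the
discrimination filter yet are uncorrelated with everything within the PPID
group); *redundant* items copy another item's underlying draw plus small
noise. The default survey-bank preset plants the published ledger's shape
(7 non-discriminating, 5 noise, one redundant demeanour pair); a compact
12-item `planted-12` bank (2 non-discriminating, 1 noise, 1 redundant pair)
is used for repeated recovery experiments.

Default effect sizes were fixed once while designing the generator:
β_PPID = 0.70, β_chronic = 0.45, β_age = 0.30 per pooled age-SD, loading
a = 0.80. These give a group score separation of the same order as reported
field medians (≈0.42 vs ≈0.24 here against 0.33 vs 0.20 in the field), a
moderate global-QoL anchor correlation (≈0.5), and item-total correlations
comfortably above the 0.30 pruning criterion, matching the wide margins the
published retained items show. The resulting synthetic internal consistency
(α ≈ 0.93) is higher than the reported field value (0.835): the generator's
single-factor structure has no domain-specific variance, a known gap
documented below. Owner QoL ratings are cut from a noisy linear function of
θ at points matched to the reported rating marginal (≈52/42/5/1/0.3%).
Years-since-diagnosis is log-normal with median 2 and log-sd 1.33 (matched
to the reported 1–6 interquartile ratio; a two-parameter log-normal cannot
match the median and both quartiles simultaneously). Sex is binary
(mare/gelding): stallions are <1% of aged cohorts and a level with a couple
of observations cannot support the factor × covariate interaction design.

The rater model shares each subject's true score between two raters (or two
occasions of one rater) with per-rater offsets (sd 0.02) harming absolute
agreement only, and occasion noise (sd 0.045). For variance-component
recovery experiments, subject scores can instead be drawn N(0, σ_b²) so
that the consistency ICC targets σ_b²/(σ_b² + σ_e²).

All randomness flows from one `numpy` Generator seeded by the caller;
identical parameters and seed give byte-identical tables.

### What passing tests do and do not show

The generator's single latent factor, independent item noise and clean
planted structure are idealizations: real owner data have correlated domain
clusters, response styles, and missingness, none of which are simulated.
Recovery of the planted dispositions therefore demonstrates that the
pipeline implements its selection rules correctly and is well calibrated
(type-I rates near nominal, null p-values uniform), not that the procedure
would select the same items from new field data. The field study's
data-dependent results (α = 0.835, medians 0.33/0.20, r_s = 0.466, the ICC
and F values) rest on an undeposited survey and are emulation anchors, not
reproduction targets.

## Problem sizes used in the checks

The packaged checks use the study-scale cohort (343 + 269) for pipeline
runs; 200 seeded replicates of the 12-item planted bank for refinement
recovery; 2000 replicates for the chi-squared type-I rate; 1000 reduced
cohorts (60 + 60) for GLM null calibration; ten replicate rating studies of
n = 500 per variance preset for ICC recovery (a single n = 500, k = 2 study
has sampling sd ≈ 0.04 near ICC 0.5, so replicate averaging measures the
estimator's accuracy rather than one draw's luck); and n = 200 000 for the
two-item closed-form α check.

## Known limitations

* No test–retest reliability over long horizons, factor analysis, IRT
  calibration, mixed-model (REML) estimation, or multiple-testing
  correction — all outside the implemented development process.
* No imputation for missing covariates (listwise deletion only) and no
  missing-response imputation beyond the explicit midpoint opt-in.
* The published final tool numbers its 19th item "29"; the packaged file
  renumbers sequentially 1–24.
* The published development account gives intra-rater n = 7 in its methods
  but n = 8 (ICC 0.835) in its results, with the inter-rater counts
  swapped; neither ICC is recomputable without the raw subsample, and the
  package takes no position on the swap.
* Whether the reported merged-pair correlation used all respondents or PPID
  rows only is unstated; this implementation computes merge correlations on
  PPID rows, consistent with the stated internal-consistency subsetting.
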