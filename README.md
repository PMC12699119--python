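# ppidqol

Owner-reported health-related quality-of-life (HRQoL) assessment for horses
with pituitary pars intermedia dysfunction (PPID), a common neurodegenerative
endocrine disease of older equids. The package implements the scoring rules of
a 24-item, seven-domain owner questionnaire together with the full
psychometric pipeline used to develop such an instrument, so that every stage
— item discrimination, internal-consistency refinement, reliability, validity
and association modelling — can be run, tested and audited on synthetic
cohorts with known structure.

It is aimed at veterinary epidemiologists and welfare scientists who want to
score response tables with the packaged instrument, re-run the development
pipeline with different thresholds, or study the statistical behaviour of
weighted Likert instruments under controlled simulation.

## The score

Each item maps its ordered response options to numeric scores (0 = no
negative impact, up to the item maximum of 3 or 4; positively phrased items
carry reversed scores, and "I have not been able to observe this" scores the
item midpoint so it neither inflates nor deflates the result). Items belong
to one of seven domains — demeanour, appearance, condition, health, appetite,
ingestion, management — each weighted by the median owner-rated importance
*w_d* ∈ {1..5}. For a complete response with item scores *s_i*,

```
HRQoL = Σ_i w_d(i) · s_i  /  Σ_i w_d(i) · max_i
```

which runs from 0 (best possible QoL) to 1 (worst). For the packaged
instrument and weights the denominator is 383.

## The development pipeline

Starting from the 37-item survey bank (`ppid-survey-37`):

1. **Discrimination** — per-item Pearson chi-squared test of the response
   distribution between PPID and non-PPID horses; items with p ≥ 0.05 are
   dropped as not specific to the disease.
2. **Redundancy** — within the PPID group, same-domain pairs with inter-item
   r > 0.60 are merged (they record the same information and inflate
   internal consistency).
3. **Item-total pruning** — items with corrected item-total correlation
   r < 0.30 are removed one at a time, always the removal that most
   increases Cronbach's α, until no removal helps. Adequacy requires
   α > 0.70.

Reliability uses two-way single-measure intraclass correlations
(consistency for within-observer occasions, absolute agreement between
observers), face validity a Spearman correlation of the score against the
owner's direct 1–5 QoL rating, and group comparisons of importance ratings
Stuart's Kendall tau-c. Association models are Type III GLMs of
sqrt(HRQoL) on disease status, chronic comorbidity, breed, sex, body
condition and age (plus factor × covariate interactions only).

## Worked example

```python
import ppidqol as pq

instrument = pq.load_instrument("ppid-final-24")
print("items:", len(instrument), "| max weighted score:",
      pq.max_weighted_score(instrument))

cohort = pq.simulate_cohort(pq.final_tool_params(), seed=42)
frame = pq.analysis_frame(cohort, instrument)
for grp, sub in frame.groupby("group"):
    q1, med, q3 = sub["hrqol"].quantile([0.25, 0.5, 0.75])
    print(f"{grp}: median {med:.2f} (IQR {q1:.2f}, {q3:.2f})")

r_s, p = pq.spearman_validity(frame["owner_global_qol"], frame["hrqol"])
print(f"face validity: r_s = {r_s:.3f} (p = {p:.2g})")

report = pq.fit_glm(frame, "all-horses")
print(report.to_frame().round(4).loc[["ppid", "chronic", "age"]])
```

prints

```
items: 24 | max weighted score: 383.0
non-ppid: median 0.24 (IQR 0.13, 0.42)
ppid: median 0.42 (IQR 0.24, 0.65)
face validity: r_s = 0.518 (p = 3.1e-43)
              F  df_num  df_den       p
term
ppid    38.0008       1     584  0.0000
chronic 16.5207       1     584  0.0001
age      1.8014       1     584  0.1801
```

The simulated PPID group scores roughly twice as high (worse) as the
control group; the moderate positive Spearman correlation shows the score
tracks the owners' direct QoL judgement; and the GLM detects the planted
disease and comorbidity effects while age, whose influence enters through
the latent severity, is largely absorbed by the group terms.

The same pipeline is available from the shell:

```
ppidqol simulate --seed 7 --out cohort.csv
ppidqol refine --responses cohort.csv --out report.json
ppidqol score --responses cohort.csv --instrument ppid-final-24 --out scored.csv
```

`refine` prints the full audit ledger, e.g.

```
refinement: 37 input items -> 24 retained
[chi2] drop-nondiscriminating: svy3 (chi2=2.315, df=3, p=0.5097)
...
[merge] merge-redundant: svy1, svy2 (r=0.9123)
[prune] drop-low-item-total: svy30 (r=-0.01109); alpha 0.9218 -> 0.9240
final alpha = 0.9262 (adequate criterion alpha > 0.7)
```

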