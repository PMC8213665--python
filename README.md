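# qreport

Quantitative volumetry reports for dementia imaging, and the statistics
of multi-rater studies that evaluate them.

Structural MRI is central to diagnosing neurodegenerative disease, but
visual assessment of atrophy is subjective and varies between readers.
`qreport` addresses both halves of the problem:

1. **Reporting.** It fits a *normative model* of regional grey-matter
   volume on a healthy reference population and turns a single patient's
   volumes into population percentiles, displayed as a one-page report:
   a log-radial, traffic-light **rose plot** of regional percentiles,
   hippocampal percentiles, brain parenchymal fraction (BPF) against
   normative age curves, and scan-quality metrics (SNR/CNR).
2. **Evaluation.** It analyses a forced-choice multi-rater accuracy
   study of such reports — each rater reads every scan twice, with and
   without the report — producing sensitivity/specificity/accuracy
   tables, McNemar and paired *t* tests, Cohen's κ against the confirmed
   diagnosis, Cronbach's α and ICC across raters, a mixed ANOVA on
   confidence ratings, and sample-size estimates for future studies.

A synthetic-data module generates every input such a study needs —
a normative cohort (n = 461 by default), a 45-scan test set
(15 controls, 16 Alzheimer's disease, 14 frontotemporal dementia) with
disease-specific atrophy patterns, randomised rating schedules, and
simulated raters — so the full pipeline runs and is tested end to end
with no external data.

## The model

For each region *r*, healthy-control volume is regressed jointly on age,
sex and total intracranial volume (TIV):

```
v_r = β₀ + β_age·age + β_sex·sex + β_tiv·TIV + ε,   ε ~ N(0, σ_r²)
```

A patient's standardised residual `z = (v − β·x)/σ` is mapped to a
percentile by a choice of CDF: exact Gaussian `100·Φ(z)` (default), the
logistic approximation `100/(1 + e^(−1.702 z))`, or a Richards
generalised-logistic curve `100·(1 + Q e^(−Bz))^(−1/ν)` fitted to the
reference residuals' empirical CDF. BPF = (GM + WM)/TIV gets its own
age-only normative fit, since TIV already sits in its denominator.

Study statistics follow the standard definitions: sensitivity
`TP/(TP+FN)·100`, specificity `TN/(TN+FP)·100`, accuracy
`(TP+TN)/total·100`; McNemar on discordant counts (exact binomial for
small counts); paired-design Cohen's *d* with the pooled-SD denominator
`√((SD₁²+SD₂²)/2)`; unweighted κ; α and consistency ICC(3,1)/ICC(3,k)
from a two-way mixed ANOVA.

## Worked example

```python
import qreport as q

ref = q.simulate_normative_population(seed=7)        # 461 healthy controls
model = q.fit_normative_model(ref, cdf_variant="gaussian")
cohort = q.simulate_test_cohort(seed=8)              # 15/16/14 test set
patient = next(s for s in cohort if s.group == "AD")

for r in ("hippocampus_left", "hippocampus_right", "frontal_lobe_left"):
    print(f"{r}: {q.percentile(model, patient, r):.1f}")
print(f"BPF {q.brain_parenchymal_fraction(patient):.3f} "
      f"(percentile {q.bpf_percentile(model, patient):.1f})")

_, gold, ratings = q.simulate_study(seed=9)          # nine simulated raters
res = q.analyse_study(ratings, gold)
t = res.metrics["volume_loss"]
row = t[(t.metric == "sensitivity") & (t.experience == "combined")].iloc[0]
print(f"combined sensitivity {row.without_mean:.1f}% -> {row.with_mean:.1f}% "
      f"(p={row.p_value:.3f}, d={row.cohens_d:.2f})")
```

prints

```
hippocampus_left: 2.4
hippocampus_right: 0.1
frontal_lobe_left: 68.2
BPF 0.804 (percentile 27.8)
combined sensitivity 75.6% -> 83.7% (p=0.016, d=1.40)
```

The AD patient's hippocampal volumes sit at the 2.4th and 0.1st
percentiles of the dementia-free population (deep red on the rose plot)
while frontal volume is unremarkable — the expected AD pattern. In the
simulated study, the built-in with-report sensitivity advantage of the
rater model is recovered by the analysis pipeline and detected by the
paired *t* test.

The same workflow is available from a shell:

```bash
qreport simulate cohort --seed 7 --out work/
qreport simulate raters --seed 9 --out work/
qreport fit --reference work/normative.csv --out work/model.json
qreport render --model work/model.json --subject work/cohort.csv --out work/report.html
qreport study-analyse --ratings work/ratings.csv --gold work/gold.csv --out work/results.json
```

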