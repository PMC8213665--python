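# Methods

## Normative percentile model

Each region's healthy-control volume is modelled as a single joint
ordinary-least-squares regression on age (years), sex (0 = female,
1 = male) and total intracranial volume (mL):

    v = β₀ + β_age·age + β_sex·sex + β_tiv·TIV + ε,  ε ~ N(0, σ²)

σ is the residual standard deviation with denominator n − 4. A joint
fit, rather than sequential residualisation, makes the adjustment
order-independent. Assumptions: linear age trajectories over the
reference age range, additive covariate effects, homoscedastic
Gaussian-ish residuals. Nonlinear age terms, site harmonisation and
longitudinal change are out of scope.

A patient's percentile is a CDF applied to z = (v − β·x)/σ. Three
variants are provided because the exact residual CDF used in deployed
reporting tools is rarely published and any reasonable reading falls
between them:

* `gaussian` (default): 100·Φ(z). Deterministic, parameter-free.
* `logistic_approx`: 100/(1 + e^(−1.702 z)). The classical logistic
  approximation to the normal ogive; differs from Gaussian by < 2
  percentile points for |z| ≤ 3 (asserted in tests).
* `generalised_logistic`: 100·(1 + Q·e^(−Bz))^(−1/ν), a Richards curve
  whose shape (B, ν, Q) is least-squares fitted to the pooled empirical
  CDF of standardised reference residuals (initialised at the logistic
  values B = 1.702, ν = Q = 1; bounds (10⁻³, 20) on each). This variant
  can absorb mild asymmetry in the residual distribution.

Percentiles are clipped to [0.01, 99.99] for display so the log-radial
rose axis stays finite. Degenerate inputs fail loudly: a rank-deficient
design (e.g. constant age, or one sex absent) raises a design error;
zero residual variance raises a variance error; references below n = 30
are refused.

**Brain parenchymal fraction.** BPF = (GM + WM)/TIV. Its normative
model regresses BPF on age only: TIV is BPF's denominator, and
regressing a ratio on its own denominator induces spurious structure.
The report's BPF panel draws the 5/25/50/75/95th percentile curves
across the reference age range under the Gaussian residual model.

**QC metrics.** SNR = mean WM signal / background SD and
CNR = |WM − GM| / background SD. The exact signal regions feeding these
statistics are acquisition-specific; the formulas are the documented
convention and the values pass through the report unchanged.

## Rose plot

Radius is log-scaled: radius(p) = (log₁₀(p) + 2)/4, mapping
0.01 → 0 and 100 → 1, so clinically salient low percentiles occupy most
of the radial range. Gridlines sit at {1, 5, 25, 50, 100}. Colours are
a step function of percentile with breakpoints {1, 5, 25} (red below 1,
then orange, yellow, green at/above 25) — conventional clinical alarm
levels, configurable. Sectors are equal-angle, ordered by the
user-supplied region map (lobe by lobe); equal spans keep visual weight
uniform across regions of very different absolute volume. Rendering is
plain SVG-in-HTML string assembly with fixed numeric formatting, so
identical inputs give byte-identical documents — a tested property.
The report shows age and sex only, mirroring the blinding of the rater
study; the blinding test asserts that two subjects differing only in
identity and clinical fields render identically.

## Rater-study statistics

* **Tasks.** Volume-loss detection scores all scans (positive = any
  patient, positive call = 'abnormal'). The AD-vs-normal and
  FTD-vs-normal tasks restrict to {target disease, control} scans. By
  default a true positive requires the correct sub-diagnosis
  (`strict`); `abnormal_only` counts any abnormal call, since published
  reader studies rarely state how a wrong-subtype abnormal call is
  scored.
* **Aggregation.** Group rows are mean (SD, n − 1) over each
  experience level's raters; the combined row is the unweighted mean of
  group means with the SD taken over all raters (with equal group
  sizes the two means coincide, and this reproduces the published
  combined rows exactly).
* **Cohen's d** for the paired design uses the pooled-SD denominator
  √((SD₁² + SD₂²)/2). This convention reproduces the published per-group
  effect sizes where the SD-of-differences convention does not; the
  latter remains available (`d_method="diff"`).
* **McNemar** defaults to the exact two-sided binomial when the
  discordant total b + c < 25 (study-sized counts are small) and the
  continuity-corrected χ² = (max(|b−c|−1, 0))²/(b+c) otherwise. The
  floor at zero keeps the corrected statistic ≤ the uncorrected one
  when b = c.
* **κ / α / ICC.** Unweighted Cohen's κ with explicit p_o and p_e;
  Cronbach's α with raters as items; ICC from a two-way mixed ANOVA
  without interaction in the *consistency* form, ICC(3,1) and ICC(3,k).
  Whether the original analysis used consistency or absolute agreement
  is not determinable from its description; consistency is the default
  and satisfies the algebraic identity α = ICC(3,k), which the tests
  assert to 1e-10.
* **Confidence ANOVA.** Per-rater cell means of the normality-call
  confidence in the 2×2×2 within design (report × true normality ×
  correctness), with experience (3 levels) between. Sums of squares are
  orthogonal mean-subtraction projections on the balanced table; each
  within-family effect is tested against its effect × subject-within-
  group error (df 6 with 9 raters in 3 groups), the between factor
  against subjects-within-groups. Effect sizes are partial η² =
  SS/(SS + SS_error). Missing cells raise — no imputation — so a rater
  who is never wrong excludes the ANOVA (the pipeline records the reason
  and carries on). Note this genuine mixed design yields F(1,6) error
  terms; an analysis that ignores the between factor would report
  F(1,8).
* **Sample size** for a future paired design: exact noncentral-t power
  iterated upward in n (default), or the normal-approximation closed
  form ⌈(z₁₋α/₂ + z_power)²/d²⌉.

## Synthetic data

The generator's defaults are the study conditions: a normative cohort
of n = 461 (age ~ N(70.09, 12.05²) truncated to 30–95 years, 51.4%
female) and a test set of 15 controls / 16 AD / 14 FTD with the
published per-group age, sex-ratio, MMSE and disease-duration
distributions. TIV is N(1320, 110²) mL for women and N(1460, 110²) for
men, clipped to 900–2100. Regional volumes follow the same linear
covariate law the normative model assumes, with magnitudes chosen to be
anatomically plausible (hippocampus ~3 mL, lobar GM tens of mL, total
GM ~620 mL and WM ~480 mL at age 70; parenchyma scales ~proportionally
with TIV so BPF stays within (0, 1) across head sizes).

Disease is a multiplicative volume reduction: 0.80 on the focal regions
(hippocampus/temporal for AD, frontal/insula for FTD) and 0.95
elsewhere — subtle atrophy befitting a young, short-duration clinical
cohort; both multipliers are configurable, and 1.0 recovers the null.

Simulated raters make condition-specific Bernoulli calls
(sensitivity/specificity per condition), choose the sub-diagnosis
correctly with a given probability after a correct abnormal call (a
false-positive control is labelled AD or FTD at random), and report
confidence as a Gaussian (SD 0.8) around a cell mean — base 3.0, +0.9
when correct, +0.45 for truly abnormal scans, +0.25 with the report —
rounded and clipped to the 1–5 scale. The default nine raters mirror
the published group sensitivities/specificities for volume-loss
detection (combined sensitivity 71.5% without vs 82.2% with report).
Episode schedules are seeded permutations of the 90 scan × condition
episodes keyed on (seed, crc32(rater)), so one study seed gives every
rater a distinct reproducible order; no minimum spacing between a
scan's two episodes is enforced (the original design randomised only).

What the generator does *not* emulate: segmentation error and
scanner/site effects; nonlinear ageing; learning or anchoring effects
across episodes; correlation between a rater's two readings of the same
scan beyond what the shared truth induces; borderline "worried-well"
controls (an optional concern in clinic-recruited control groups).
Passing tests therefore demonstrate internal consistency of model,
pipeline and statistics under the stated generating law — not clinical
performance on real MRI.

## Verification strategy and problem sizes

Percentile calibration draws 2,000 fresh subjects from a fitted model's
own generating process and requires per-region uniformity (KS p > 0.01).
Covariate-invariance of residual percentiles is checked in-sample at
n = 2,000 (out of sample, estimation error from an n = 461 fit alone
induces |ρ| ≈ 1/√461, which would swamp the band). Parameter recovery
runs 20 independent n = 461 cohorts; with 1,280 coefficient checks the
per-check 3-SE band is enforced through its binomial exceedance
envelope (≤ 12 exceedances, all |z| < 6) rather than as 1,280
simultaneous hard bounds, and σ̂ analogously (rel. SD ≈ 3.3%, band 10%,
≤ 5 exceedances, hard cap 20%). Statistical routines are verified
against independent implementations (scikit-learn κ, pingouin α/ICC,
statsmodels McNemar and power, scipy paired t, and a regression-
projection oracle for the mixed ANOVA) to 1e-8 on 100 random instances
each. End-to-end recovery uses 50–200 simulated studies depending on
the check; the simulated with-report sensitivity gain is compared with
its generating value within the analytically propagated binomial error.
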