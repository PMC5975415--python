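# Methods

## The classification rule

The package scores a five-marker serum panel (CA 125, β2-microglobulin,
transferrin, apolipoprotein A1, prealbumin) without proprietary scoring
software. Each marker is dichotomized against its laboratory reference
range in the direction associated with malignancy: CA 125 and
β2-microglobulin are positive above their upper limits, the three transport
proteins below their lower limits. CA 125's cutoff is menopause dependent
(200 IU/L premenopausal, 35 IU/L postmenopausal — the gynecologic-oncology
referral criteria), and the same cutoffs are used inside the panel vote and
for the standalone CA 125 test; no separate within-panel cutoff is defined
anywhere, so the two uses share one rule. A panel with ≥ 3 positive markers
is high risk, ≤ 2 low risk.

Boundary convention: the reference-range labels say "above the upper
limit" / "below the lower limit", so all comparisons are strict; a value
exactly at a limit is negative. A panel with any missing marker raises an
error identifying the absent markers — a triage rule must not silently
degrade to a 3-of-4 vote.

Menopause is derived from the menstrual history: amenorrhea ≥ 12 months, or
age ≥ 50 when the woman is unsure of her menses. The age rule applies
*only* when she is unsure; a woman with known amenorrhea of 11 months at
age 55 is premenopausal under this definition. Unknown months without the
unsure flag is treated as a contradictory record (validation error), never
imputed.

Categorical derivations used by the association analysis: parity 0 /
1–4 / ≥ 5; BMI < 25 / [25, 30) / ≥ 30 (the "25–29" label is read as the
WHO convention [25, 30), which assigns the otherwise-unlabelled [29, 30)
interval to overweight); breastfeeding < 6 vs ≥ 6 months with 6.0 in the
upper class.

## Accuracy statistics

Against the histopathology gold standard, the 2×2 cells give the standard
percentages (sensitivity, specificity, PV⁺, PV⁻, total agreement). A ratio
with a zero denominator is reported as *absent*, never as 0 or 100 —
silent extremes would corrupt comparisons across strata.

**Exact McNemar.** The paired comparison of a test with the gold standard
uses the exact two-sided binomial form on the discordant cells (b = FP,
c = FN): p = min(1, 2·P(Binomial(b+c, ½) ≤ min(b, c))), p = 1 when
b + c = 0. The exact form (not the χ² approximation, not
continuity-corrected) is the variant that reproduces the reference values
0.267 (b=4, c=9), 0.004 (20, 5) and 0.169 (17, 9); it is doubled-smaller-
tail, capped at 1 — the convention of the major statistics packages.

**Association tests.** Pearson chi-square without Yates correction
(only the uncorrected statistic reproduces the reference p = 0.386 at
χ² = 0.75 and p = 0.048 at χ² ≈ 6.06, df 2), with expected counts
E_ij = n_i·n_j/n. When *strictly more than* 20% of expected counts are
below 5 (exactly 20% still permits chi-square), a 2×2 falls to the
two-sided Fisher exact test: the sum of hypergeometric point probabilities
≤ the observed table's, with a 1e-7 relative guard on the comparison so
floating-point noise cannot exclude exact ties (point probabilities come
from scipy's hypergeometric pmf, which is log-gamma based and stable at
n = 150). Fisher for tables larger than 2×2 is deliberately unsupported —
the analyses this package targets never need it. One analysed table (BMI,
with a zero observed cell) has 1 of 6 expected counts below 5 (16.7%), so
chi-square is correctly selected despite the sparse-looking row; the rule
is applied to expected, not observed, counts.

**Reconstruction from summaries.** Cohort size n, disease positives d,
test positives t and the printed agreement g (%) determine the cells
through tp = (a + t + d − n)/2 with a = tp + tn the agreement count.
Since the printed g is rounded, a is searched over round(g·n/100) ± 1;
parity of a + t + d − n eliminates every second candidate and candidates
two apart change the recomputed agreement by ≥ 0.4 points at n ≤ 500, so
the solution matching g to 1 decimal place is unique. Inconsistent
summaries raise an error listing each violated constraint.

**Stage stratification** pools the malignant cases of a FIGO group
(early I–II, late III–IV) with the *entire* benign arm, mirroring how
stage-stratified screening tables are published; a case-only subset would
change specificity.

Rounding is applied only at render time (percentages 1 dp, p-values 3 dp,
"< 0.001" below 0.0005); all internal computation is full precision.

## The synthetic reference cohort

No per-patient data accompany the study the package models, but its
summary tables fully determine the integer confusion cells of every test
(via the reconstruction above) and every risk-factor count.
`study_data.build_reference_cohort()` materializes one deterministic
SYNTHETIC 150-patient cohort consistent with *all* of them
simultaneously: 30 malignant (FIGO 4/4/11/11), index-assay cells
(21, 4, 9, 116) with all 8 early-stage cancers assay-positive, CA 125
cells (25, 20, 5, 100), clinician cells (21, 17, 9, 103) overlapping the
assay on 14 malignant and 0 benign patients (which fixes the parallel
combination at 28/30 sensitivity and 99/120 specificity), every
risk-factor row, and the subtype table. Joint structure the summaries do
not constrain is an arbitrary deterministic assignment, and marker values
are round numbers placed on the correct side of each patient's thresholds
— the cohort is an audit fixture, not an imputation of the real patients.

## The cohort simulator

`generate_cohort` draws, per patient: class (Bernoulli at 20% prevalence),
menopause (24/30 postmenopausal given malignant, 14/120 given benign),
FIGO stage (13/13/37/37%), risk-factor covariates at the class-conditional
reference proportions, log-normal marker levels, and a clinician
impression that is Bernoulli(sensitivity 0.70) for malignant and
Bernoulli(1 − specificity 0.858) for benign. One integer seed drives a
single generator stream; records are emitted in generation order and all
pass cohort validation.

Marker levels are log-normal — serum tumor markers are positive and
right-skewed — and independent within class by default. That independence
makes calibration analytic: with per-marker positivity rates p₁…p₅ the
panel's exceedance P(≥ 3 positive) is a Poisson-binomial tail, enumerated
exactly over the 2⁵ patterns. `calibrated_params()` targets CA 125 at its
reference standalone operating point (83.3% / 83.3%) and solves a shared
rate for the four protein markers so the panel lands at 70% / 96.7%:
q ≈ 0.55 per protein marker given malignant, q ≈ 0.16 given benign. Scale
parameters are fixed (σ = 1.0 for CA 125, 0.6 for the proteins — spreads
of roughly e^σ typical of serum assays); locations then follow in closed
form from μ = log(cutoff) − σ·Φ⁻¹(·), except CA 125, whose
menopause-dependent cutoff makes its class rate a two-component mixture
solved by Brent's method over the class's menopause mix. Because the
panel tail is linear in any single marker's rate, mixing over menopause
commutes with the tail calculation and the analytic operating point is
exact, not approximate.

An optional Gaussian-copula correlation across markers exists (default
off) because real panels correlate; switching it on preserves each
marker's marginal positivity rate but invalidates the independence-based
panel calibration, which is why it is not the default. Ages, months of
amenorrhea, parity counts and BMI values within class are drawn uniformly
from plausible clinical ranges; they carry no information beyond their
class labels.

What passing the simulation tests shows — and does not. The generator
reproduces the *marginal* structure the analysis assumes (prevalence,
operating points, stage mix, covariate rates). It does not model assay
measurement error, marker–covariate dependence (e.g. CA 125 rising in
endometriosis), batch effects or verification bias, so simulation results
validate the pipeline's arithmetic, not the clinical performance of the
rule on new populations.

## Problem sizes and determinism

Large-sample checks use n = 30 000 in the unit suite and n = 100 000 in
the acceptance script — sizes at which the 3-standard-error bands on the
recovered probabilities are a few tenths of a percentage point, while a
full run stays in seconds. Hypothesis property tests run derandomized;
every stochastic check is seeded. Report JSON is rendered with sorted keys
so identical inputs give byte-identical output.

## Known limitations

- The clinician impression is simulated conditionally independent of the
  marker values given class — the simplest model consistent with
  separately reported operating points; real clinicians see CA 125.
- The 3-of-5 vote is fixed; no ROC tuning or threshold optimization is
  provided (deliberately out of scope: the rule's value is that it needs
  no fitting).
- No confidence intervals for sensitivity/specificity and no effect-size
  measures for associations, matching the summary-table format the
  pipeline reproduces.
- Fisher's exact test is 2×2 only; the subtype table is descriptive.
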