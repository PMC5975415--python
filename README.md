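# miascreen

Pre-operative triage of ovarian masses with a **software-independent
multivariate index assay (MIA)**, plus the complete statistical machinery to
evaluate any such screening test against surgical histopathology.

## The problem and the method

Distinguishing benign from malignant ovarian masses before surgery is hard:
no single ultrasound finding or serum marker is reliable, and CA 125 alone
misses a large share of early-stage cancers. The commercial five-biomarker
index assay improves triage but requires proprietary scoring software that
is unavailable in many settings. `miascreen` implements the
cutoff-based alternative: score each of the five serum markers against its
laboratory reference range and call the mass **high risk when at least 3 of
the 5 markers are positive**.

| marker | reference range | positive when |
|---|---|---|
| CA 125 | ≤ 200 IU/L (premenopausal), ≤ 35 IU/L (postmenopausal) | above the cutoff |
| β2-microglobulin | 1.22–2.46 g/L | above the upper limit |
| transferrin | 2.24–4.06 g/L | below the lower limit |
| apolipoprotein A1 | 1.24–2.02 g/L | below the lower limit |
| prealbumin (transthyretin) | 0.216–0.328 g/L | below the lower limit |

All comparisons are strict; a value exactly at a limit is within the normal
range. Thresholds are configurable (YAML) so other kits' ranges can be
substituted.

Around the classifier, the package provides the full evaluation pipeline in
standard diagnostic-accuracy notation. For a 2×2 of test vs gold standard
(TP, FP, FN, TN):

- sensitivity = TP/(TP+FN)·100, specificity = TN/(FP+TN)·100,
  PV⁺ = TP/(TP+FP)·100, PV⁻ = TN/(FN+TN)·100,
  total agreement = (TP+TN)/n·100;
- **exact McNemar test** on the discordant cells b = FP, c = FN:
  p = min(1, 2·P(X ≤ min(b,c))) with X ~ Binomial(b+c, ½);
- risk-factor association by Pearson chi-square (no continuity correction)
  or, when more than 20% of expected counts E_ij = n_i·n_j/n fall below 5,
  the two-sided Fisher exact test (sum of hypergeometric point
  probabilities ≤ the observed one);
- **reconstruction of integer 2×2 cells** from published summaries (cohort
  size, disease positives, test positives, agreement %) — useful for
  auditing reports that print only marginals;
- FIGO-stage-stratified evaluation (early = I–II, late = III–IV, each
  pooled with the full benign arm), parallel test combination (OR), a
  calibrated synthetic cohort generator, and a one-command study report.

It is aimed at clinical researchers and biostatisticians who want to
evaluate or audit cutoff-based triage rules, especially in low-resource
settings without access to proprietary scoring software.

## Worked example

```python
from miascreen import MarkerPanel, MenopausalStatus, mia_classify

panel = MarkerPanel(ca125=48.0, b2m=2.9, transferrin=1.8,
                    apoa1=1.5, prealbumin=0.27)
result = mia_classify(panel, MenopausalStatus.POSTMENOPAUSAL)
print(result.n_positive, result.high_risk)   # 3 True
```

Three markers (CA 125 > 35 IU/L, β2-microglobulin > 2.46 g/L, transferrin
< 2.24 g/L) are positive, so the panel votes high risk.

Evaluating all tests on the bundled synthetic reference cohort — a
deterministic 150-patient cohort (30 malignant) constructed to match the
summary tables of the study the package models — prints
(`python examples/02_evaluate_tests.py`):

```
test                 sens   spec    ppv    npv  agree  McNemar p
mia                  70.0   96.7   84.0   92.8   91.3      0.267
ca125                83.3   83.3   55.6   95.2   83.3      0.004
gynecologist         70.0   85.8   55.3   92.0   82.7      0.169
mia_or_clinical      93.3   82.5   57.1   98.0   84.7    < 0.001
```

The index assay trades some sensitivity against CA 125 for much higher
specificity and positive predictive value; OR-combining it with the
clinician's impression lifts sensitivity to 93.3% at a specificity cost.
A McNemar p above 0.05 (e.g. 0.267) means the test's calls are not
detectably asymmetric against histopathology on the discordant pairs.

The other scripts in `examples/` cover risk-factor association
(chi-square/Fisher selection), cohort simulation and calibration,
the full study report, and 2×2 reconstruction from summaries. The same
capabilities are exposed on a thin CLI:

```bash
miascreen simulate --seed 1 --n 150 --out cohort.csv
miascreen run --cohort cohort.csv --out report/
miascreen reconstruct --n-total 150 --n-disease-pos 30 --n-test-pos 25 --agreement-pct 91.3
```

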