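# incns

Tools for scoring comatose neurocritical-care patients and validating severity
scales against binary outcomes in a paired design.

Prognosis in deep coma is usually judged at the bedside with severity scores.
The INCNS score (Inflammation, Nutrition, Consciousness, Neurological
function, Systemic function) is a 19-item instrument, 0–44 points with higher
meaning worse, that combines a neurological exam with labs and vital signs.
This package implements INCNS exactly from its published item band tables,
alongside the three standard comparators used in its validation — the Glasgow
Coma Scale (GCS, 3–15, lower worse), the FOUR score (0–16, lower worse) and
APACHE II (0–71, higher worse) — plus everything needed to run the full
validation study design:

- **Cohort pipeline** — coma eligibility (GCS E = 1, V ≤ 2, M ≤ 4 on the
  earliest exam), exclusion of short stays (< 72 h) and drug-induced coma,
  per-variable *worst-in-window* scoring over the first 24 and 72 h, and mRS
  dichotomization (mRS < 3 favorable) into three nested binary outcomes
  (unfavorable outcome ⊇ 3-month death ⊇ NICU death).
- **Paired diagnostic statistics** — empirical AUC with DeLong variance and
  logit confidence intervals; the paired DeLong z-test for correlated AUCs
  (AUĈ = Σᵢⱼ[𝟙(xᵢ > yⱼ) + ½𝟙(xᵢ = yⱼ)]/(mn)); Youden-index cut-offs
  (max J = Se + Sp − 1); confusion metrics including balanced accuracy
  (Se + Sp)/2; McNemar tests for paired Se/Sp/CC; a generalized score test
  for paired PPV/NPV; Bonferroni alpha adjustment; and reconstruction of full
  confusion tables from published Se/Sp percentages and class counts.
- **Synthetic cohort generator** — a latent-severity simulator that emulates
  a 271-patient comatose NICU cohort (83% unfavorable, 45% 3-month death,
  9.6% NICU death) with repeated observations over 72 h, nested outcomes, and
  a closed-form binormal AUC calibration (Δ = √2·Φ⁻¹(AUC)), so every pipeline
  stage is testable without patient data.

The analysis surface follows the statsmodels convention: a `ScoreValidation`
model built from a cohort DataFrame whose `fit()` returns a
`ValidationResults` with estimates, intervals, tests, `summary()` and
`plot_roc()`.

## Worked example

```python
from incns import (SimulationConfig, ScoreValidation, build_cohort,
                   cohort_to_frame, generate_cohort)

timelines = generate_cohort(SimulationConfig(n_patients=271, seed=7))
rows, exclusions = build_cohort(timelines)          # 245 included, 26 excluded
frame = cohort_to_frame(rows)
results = ScoreValidation(frame, outcome="unfavorable", window=72).fit()
print(results.summary())
```

```
Score validation  outcome=unfavorable  window=72 h  n=245 (200 positive)
=====================================================================
 scale   AUC      95% CI    cutoff Se%  Sp%  PPV% NPV% CC%  pred.acc%
---------------------------------------------------------------------
  incns 0.795 (0.708-0.861)     12 92.5 55.6 90.2 62.5 85.7      74.0
apache2 0.777 (0.698-0.840)     17 70.5 80.0 94.0 37.9 72.2      75.3
   four 0.790 (0.705-0.856)      6 70.0 77.8 93.3 36.8 71.4      73.9
    gcs 0.785 (0.705-0.848)      5 85.0 57.8 89.9 46.4 80.0      71.4
---------------------------------------------------------------------

Paired DeLong AUC tests (alpha=0.0083)
==============================
scale A scale B   z      p
------------------------------
  incns apache2  0.854 0.3929
  ...
```

Each row gives one scale's AUC for discriminating the unfavorable 3-month
outcome from the 72-h worst scores, its DeLong 95% CI, the Youden cut-off and
the confusion metrics at that cut-off (pred.acc is balanced accuracy,
(Se+Sp)/2). The second table tests each pair of correlated AUCs with the
paired DeLong z-test at the multiplicity-corrected alpha; a third table (not
shown) compares the reference scale's thresholded Se/Sp/CC (McNemar) and
PPV/NPV (generalized score test) against each comparator.

The same pipeline is available from the shell:

```sh
incns simulate --seed 7 --n-patients 271 --out obs.csv --outcomes outcomes.csv
incns score --scale incns --input obs.csv --out scores.csv
incns build-cohort --input obs.csv --outcomes outcomes.csv \
      --out cohort.csv --log exclusions.jsonl
incns validate --cohort cohort.csv --outcome unfavorable --window 72 \
      --out results.json
```

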