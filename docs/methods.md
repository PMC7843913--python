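# Methods

## Scales

**INCNS.** Nineteen items in five domains — inflammation (WBC, axillary
temperature), nutrition (albumin), consciousness (arousal, awareness),
neurological function (pupillary and corneal reflexes, verbal response, motor
response, swallowing, respiration) and systemic condition (age, heart rate,
SBP, glucose, sodium, potassium, creatinine, bilirubin). Each item scores
0–3 points from closed bands; the per-item maxima sum to 44 (4 + 2 + 6 + 15 +
17 by domain), which the package derives from the band tables rather than
hard-coding. The motor item records the *worst* limb: both limbs with Lovett
strength ≤ 1 score 3, one limb ≤ 1 scores 2, a worse limb of 2–3 scores 1 and
both ≥ 4 score 0; alternatively the motor response to pain is scored
(obeying 0, localizing/withdrawal 1, flexing/extending 2, none 3). Either
rubric is accepted; if both are supplied the strength rubric wins and the
breakdown notes say so. Respiration scores 0/1 from the respiratory rate when
not intubated (12–24 normal) and 2/3 from the ventilator interaction
otherwise.

Two printed cells of the item sheet are internally inconsistent and are
resolved as follows. The 2-point WBC band is taken as the complement of the
0/1-point bands (≤ 2.8 or ≥ 25.1 ×10⁹/L), which keeps every WBC value
scoreable and the item maximum at 2 as the 44-point total requires. The
creatinine 0-point band is read as 44–132 µmol/L, consistent with the
1-point band "≤ 43". The pupillary/corneal rows genuinely skip the 1-point
column (0 → 2 → 3) and are implemented as printed.

**Band arithmetic.** All interval endpoints are inclusive as printed. Inputs
are quantised to each item's printed resolution (one decimal for labs, whole
numbers for rates/pressures/ages, 0.01 for pH) by decimal round-half-up
before lookup, so values such as WBC 10.05 land in the 10.1–25.0 band. After
quantisation the implemented bands tile the grid, so the residual rule —
assign a still-unmatched value to the nearest band, preferring the
higher-point one — is a conservative safety net rather than a common path.

**Comparators.** GCS is E+V+M with the dominant clinical convention that an
intubated patient's verbal component is 1 (recorded in the notes). FOUR is
the sum of its four 0–4 components. APACHE II is the 12-variable acute
physiology score (0–4 points each; creatinine in µmol/L with points doubled
under acute renal failure; the GCS item contributes 15 − GCS; oxygenation
scored from the A–a gradient when FiO₂ ≥ 0.5 and from PaO₂ otherwise) plus
age points (0–6) and chronic-health points (0/2/5), maximum 71.

**Missing data.** Scorers raise a `MissingItemError` by default. An explicit
`assume_normal_missing` flag imputes the 0-point band per missing item and
records each imputation in the breakdown notes. Silent imputation is never
performed.

## Cohort pipeline

Eligibility is judged on the *earliest* recorded exam (emergency-room
arrival): coma means GCS eye = 1, verbal ≤ 2 and motor ≤ 4. Patients with a
NICU stay under 72 h or drug-induced coma are excluded; exclusions are logged
with a single primary reason in the priority order non-comatose → short stay
→ drug-induced (→ lost to follow-up, if the optional flag is used). The
order is an implementation choice; it only affects which reason is logged for
multiply-ineligible patients, never who is excluded.

Worst-in-window scoring is **per variable**: for each scored item
independently, the most adverse value among observations in [0, window] hours
is taken (highest item points for INCNS/APACHE II, lowest component for
GCS/FOUR) and the composite worst-case observation is scored. Because every
total is the sum of its item points, this equals the itemwise adverse
aggregate of the per-observation breakdowns, and it makes the 72-h score
automatically at least as adverse as the 24-h score. A `worst_total` method
(most adverse single observation) is available for sensitivity analysis. An
observation at t = 0 counts as inside the window.

Outcomes: mRS < 3 at three months is favorable; death (mRS 6) is always
unfavorable; NICU death implies 3-month death. These nesting invariants are
enforced on construction of every timeline.

## Diagnostic statistics

The AUC is the Mann–Whitney statistic (ties count ½). Its variance uses the
DeLong structural components; the 95% CI is computed on the logit scale and
back-transformed, which respects the [0, 1] range; with zero DeLong variance
(e.g. perfect separation) the CI collapses to the point estimate with a
warning. A stratified percentile bootstrap CI is available behind a flag.
Paired AUCs are compared with the DeLong z-test on the paired component
covariance; each score carries its own severity orientation (higher-positive
for INCNS/APACHE II, lower-positive for GCS/FOUR).

Cut-offs maximise Youden's J over the observed scores, with predicted
positive defined as score ≥ threshold (higher-positive) or ≤ threshold
(lower-positive). Ties in J are broken toward higher sensitivity — in
prognostic screening a missed death is costlier than a false alarm — then
toward the more inclusive threshold; both choices are deterministic and
configurable in review.

"Predictive accuracy" as reported by clinical validation studies is
implemented as balanced accuracy (Se + Sp)/2. This is an inference, not a
quoted definition: the identity reproduces all six published panel values
(70.5, 82.6, 77.4, 83.6, 72.4, 77.9), which the acceptance tests verify.

Paired Se, Sp and CC are compared with McNemar's test on the appropriate
subject subsets (cases for Se, non-cases for Sp, everyone for CC): exact
binomial on the discordant pairs when they number fewer than 25, chi-square
with continuity correction otherwise (statsmodels backend). Paired PPV/NPV
use a generalized score statistic: among predicted-positive records (two
correlated records for a subject positive on both scores) the score for a
test-identity effect on the outcome is divided by its subject-clustered
empirical variance and referred to χ²₁. Simulation at n = 300 under an
exchangeable null puts its type-I error at ≈ 0.05, which the suite re-checks;
a subject-resampling bootstrap version is available as the validation
alternative. Multiplicity: AUC comparisons use alpha 0.05/6 → 0.0083
(round-half-up to four decimals), thresholded metrics 0.05.

Percentages are rounded half-up to one decimal **only at the reporting
layer** (binary floating-point round-half-even would corrupt e.g. 82.55 →
82.5); all internal computation is at full precision.

Confusion tables can be reconstructed from published Se/Sp percentages and
class counts by tp = round(Se·n₊), tn = round(Sp·n₋) (half-up). Of the six
published panels, five round-trip exactly; the 72-h NICU-mortality panel
prints Sp 82.5% while every integer table compatible with the 26/245 class
counts yields 82.4% — a documented print inconsistency, asserted as such.

## Synthetic cohort generator

One latent severity factor z per patient drives everything. The unfavorable
outcome is drawn first at its configured prevalence and z | y ~ N(Δ·y, 1)
with Δ = `latent_effect`. This is distributionally identical to logistic
thresholding of z (the posterior P(y|z) is expit-linear) and makes the
binormal calibration exact: `calibrate_effect_for_auc(a)` = √2·Φ⁻¹(a) gives a
latent AUC of exactly *a* for the unfavorable outcome in expectation, with
`closed_form_auc` as the oracle. The nested mortality outcomes are selected
within the unfavorable class with probability expit(b·(z − m)), b =
`mortality_steepness` × Δ, the offsets m solved by Gauss–Hermite quadrature
so marginal prevalences match in expectation. Scaling b by Δ means a null
generator (Δ = 0) carries no score–outcome association for any outcome. The
default steepness 1.2 puts the latent AUCs in the order NICU death >
3-month death ≥ unfavorable (≈ 0.89 / 0.84 / 0.80 at the default
calibration), the ordering seen in real comatose cohorts.

Observed severity at time t is s(t) = z + drift·t with drift 0.005 SD/h by
default — patients tend to worsen over the first days, which is also why
72-h worst scores discriminate slightly better than 24-h ones in generated
cohorts. Each scorer input is a monotone link of s plus item-specific
Gaussian noise (SD 0.5 by default): labs drift into higher-point bands and
GCS/FOUR components fall as severity rises. Links are deliberately
**one-sided**: each variable is perturbed in a single clinical direction
(leukocytosis, fever, hypertension, hypernatraemia, …) and clipped at the
healthy edge of its zero-point band. Two-sided links would let low-severity
patients wander into the *low* abnormal bands (bradycardia, hypoglycaemia)
and break the monotone severity→score link that the calibration tests rely
on. Consequently the generated cohort contains no hypo-excursions, no
leukopenia and no acid–base alkalosis: a stated simplification.

Defaults mirror the study conditions: 271 patients, prevalences
0.83/0.45/0.096, observation schedule {2, 12, 24, 48, 72} h, latent effect
calibrated for AUC 0.80 (the middle of the range such scores achieve), and
small exclusion arms (3% non-comatose, 4% short stay, 2% drug-induced; loss
to follow-up off by default). All included-arm patients are clamped to the
coma criteria at their first observation — the cohort is comatose on arrival
by definition — and the non-comatose arm is clamped to fail the eye
criterion. Age is drawn from a plausible NICU distribution (≈ N(55, 17),
16–94) but independently of z; in real cohorts age correlates with outcome,
so generated APACHE II/INCNS age items carry no signal. Etiology labels are
drawn at the published proportions (32.5% infarction, 23.2% CNS infection,
18% hemorrhage, remainder other) and are decorative.

A single seeded `numpy` generator drives every draw in a fixed order, so one
seed yields byte-identical CSVs. `generate_cohort(cfg, return_latent=True)`
exposes the latent table for calibration diagnostics.

**What passing tests show, and what they do not.** The generator shares the
real cohort's marginals, nesting structure, observation cadence and a
plausible severity–score link, but it assumes a *single* latent factor with
independent item noise; real inter-item correlation structure (organ-system
clustering, ventilation–arousal coupling) is unpublished and not modelled.
Tests passing on generated data therefore validate the scoring arithmetic,
the pipeline mechanics and the statistical machinery's calibration — not the
clinical performance of any scale on real patients, and the published cohort
AUCs are deliberately not reproduction targets.

## Problem sizes and numerical choices

The suite validates AUC machinery with 500-replicate CI-coverage and
1000-replicate type-I simulations at n = 200–300, generator calibration at
n = 1000–2000, and the full end-to-end validation (four scales, two windows,
three outcomes, all pairwise tests) at n = 2000 — sizes chosen to bound
Monte-Carlo error well below the asserted tolerances while keeping the whole
suite under a minute of compute for the statistical parts. Root-finding for
the selection offsets uses Brent's method on an 81-node Gauss–Hermite grid
(absolute tolerance 1e-12). Degenerate inputs (single-class labels, zero
discordant pairs, zero predicted positives, zero DeLong variance) raise or
return explicit degenerate results with notes — never silent NaNs.

## Known limitations

- APACHE II uses the axillary temperature supplied to INCNS; the original
  instrument specifies core temperature. The serum-bicarbonate fallback for
  pH is not implemented (blood gas pH is always generated/required).
- The generator's one-sided severity links exclude hypo-direction
  pathology, and age is severity-independent (see above).
- `reconstruct_confusion` assumes the published Se/Sp were themselves
  rounded half-up from integer tables; for a panel where that fails the
  reconstruction is flagged rather than forced.
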