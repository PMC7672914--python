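# Methods

## The model

TRISS assigns each trauma patient a survival probability through a fixed
logistic model, `Ps = expit(b0 + b1·RTS + b2·ISS + b3·A)`. It assumes (i) the
coded physiology bands capture the prognostic content of GCS, systolic BP and
respiratory rate; (ii) anatomical burden is summarised by ISS, i.e. the three
worst body regions with squared severities and no interaction terms; (iii) a
single age dichotomy at 55 years; and (iv) coefficients transported from the
reference cohort they were fitted on remain calibrated. The validation
machinery in this package exists to audit assumption (iv): discrimination via
the rank AUC and threshold metrics, calibration via observed/expected
survivor ratios over six Ps intervals.

Default coefficients are the MTOS blunt set (−0.4499, 0.8085, −0.0835,
−1.7430) with RTS weights (0.9368, 0.7326, 0.2908) and an age threshold of
55 years; all are injectable (`TrissCoefficients`, YAML/JSON). Pediatric
cohorts never trip the age term, so for them the model is effectively
two-predictor. No refitting is implemented: the package validates a given
coefficient set, it does not estimate one.

## Cohort definition and missing data

The inclusion filter runs in a fixed order — age ≤ 18, blunt mechanism, no
cardiac arrest on arrival, outcome known, TRISS predictors complete (age, all
six AIS regions, GCS, sBP, RR) — and each excluded record is charged to the
first rule it fails. This first-rule-wins attribution is the only way the
stage counts of a disposition flow diagram are well defined when exclusion
reasons overlap (a record can simultaneously lack outcome and predictors);
marginal per-field missingness is reported separately by
`missingness_report`, with the supplied record set as denominator and
percentages at one decimal. Analysis is complete-case throughout; no
imputation.

## Validation conventions

- **Positive class is survival.** With ~2% mortality, the reported
  sensitivity ≈ 99.5% regime only makes sense with survivors as positives.
- **Classification threshold** defaults to Ps ≥ 0.5 (configurable). At that
  cutoff whole Ps intervals become single-prediction strata, which produces
  the characteristic degenerate rows (sensitivity 100/specificity 0 above the
  cutoff, the reverse below it); metrics with a zero denominator are printed
  as 0.0 rather than NaN, matching registry-table convention.
- **Ps intervals.** Ps is rounded half-up to 2 decimals and matched to the
  closed intervals 0.00–0.25, 0.26–0.50, 0.51–0.75, 0.76–0.90, 0.91–0.95,
  0.96–1.00. The rounding closes the label gaps (0.253 → 0.25 → lowest bin;
  0.255 → 0.26 → second bin) and makes the assignment exhaustive and
  disjoint, which the tests verify by enumerating the 2-decimal lattice.
- **Expected survivors** in an interval are `round3(mean Ps) × n`; the O/E
  ratio divides observed survivors by this *unrounded* product and is
  displayed at 2 decimals, while the expected count itself is displayed as a
  half-up integer. Using the 3-decimal mean keeps the printed triple
  (mean Ps, n, expected) internally consistent (e.g. 0.130 × 172 = 22.36 →
  shown as 22, O/E 48/22.36 = 2.15, not 48/22).
- **AUC** is the two-sample midrank statistic (probability a random survivor
  outranks a random non-survivor, ties ½), so it equals exhaustive pairwise
  enumeration exactly; the 95% CI uses the DeLong structural-component
  variance, truncated to [0, 1]. Strata with a single outcome class report
  threshold metrics but an undefined AUC.
- **Group comparisons** use Mann–Whitney U (2 groups) or Kruskal–Wallis (>2)
  for continuous variables and Pearson chi-square *without* continuity
  correction for categorical ones; degenerate inputs (all tied, zero
  marginals) warn explicitly instead of returning silent NaNs.
- All display rounding is half-up (`round_half_up`); Ps is carried at full
  precision internally and only rounded for display and bin assignment.

## The synthetic registry generator

No public pediatric national-registry extract exists at this granularity, so
`synth` generates one with a known truth. Per patient: an age group (default
sizes 330/2,183/5,950/9,282, the reference cohort's mix) and uniform age
within it; per-region severe injury (AIS 3–5) with age-group-specific
probabilities (severe head injury in 81% of neonates/infants down to 31% of
adolescents; chest and extremity injuries rising with age), otherwise a
possible minor injury (AIS 1–2); physiology on the raw scale, degraded with
severity — GCS conditional on head/neck AIS (means 15 → 4 as AIS goes 0 → 5),
systolic BP dropping and respiratory rate dispersing with worst-region AIS.
Survival is then drawn as Bernoulli(expit(γ·b + δ)) where `b` is the TRISS
linear predictor under the truth coefficients. With γ=1, δ=0 the registry is
perfectly calibrated **by construction** — the property the validation stage
must recover (O/E → 1 in every interval as n grows) — and a positive logit
offset δ makes the model underestimate survival most where Ps is low, the
directional pattern reported for real pediatric cohorts. Ineligible records
(overage, penetrating, burn, arrest) and MCAR per-field, per-age-group
missingness (heaviest in neonates/infants, overall marginals near
outcome 9%, GCS 7%, sBP 6%, RR 15%, AIS 3%) exercise the filter and the
missingness accounting; exact per-cell rates are config placeholders, not
published values.

Physiology parameters were fixed once so that the scored default cohort
matches the published marginal structure of its reference: median Ps 0.99,
Ps-interval shares ≈ 1/2/3/5/6/82% from lowest to highest, ISS median 10,
RTS median 7.84, rank AUC ≈ 0.92 under perfect calibration. Two deliberate
departures from the real cohort's printed table: observed mortality under the
*calibrated* generator is ≈5%, not 2.1% — the real cohort's lower mortality
is exactly the miscalibration (O/E > 1) the method is meant to detect, and
reproducing it requires δ > 0, not different defaults; and the generator's
RTS lower quartile (≈6.9) sits below the printed 7.55, a consequence of
continuous physiology noise. What passing tests show is therefore that the
pipeline recovers known calibration truth and known marginal structure; they
cannot show that the generator reproduces the joint distribution of any real
registry (regional correlations, informative missingness, secular trends are
all absent).

## Problem sizes and numerics

Calibration-recovery checks run at n = 200,000 (groups scaled
proportionally, missingness and ineligibility zeroed via
`SynthConfig.calibration`), where every interval holds ≥ 2,000 patients and
the binomial noise on O/E is well inside ±0.05; discrimination and marginal
checks run at the default n = 17,745. Generation and scoring are vectorised
(numpy), so the large run takes a few seconds. Ps is clamped to the open
interval (0,1) against float saturation; bin matching happens on the
integer-cent lattice to avoid float-edge artefacts; ISS at AIS 6 short-
circuits to 75 before the top-three selection.

## Known limitations

- Only region-level AIS severities are consumed; dictionary coding of injury
  text to AIS is out of scope, as are penetrating/burn models and pediatric-
  specific or refitted coefficient sets (coefficients are pluggable, not
  estimated).
- Missingness is MCAR by field and age group; real registries likely miss
  physiology informatively (sicker infants are harder to assess).
- The DeLong CI is a large-sample interval; in strata with very few deaths it
  is wide and its truncation at 1.0 visible.
- The O/E ratio is reported as a point estimate (no bootstrap), mirroring
  standard registry tables.
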