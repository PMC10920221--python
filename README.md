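# pedpkd

Kidney-volume–based risk stratification for pediatric autosomal dominant
polycystic kidney disease (ADPKD).

Most children with ADPKD keep a normal glomerular filtration rate for
years while their kidneys accumulate structural damage, so function alone
is a poor early marker. Kidney volume is not: height-adjusted total
kidney volume (htTKV) measured on MRI correlates inversely with later
function and underpins the adult Mayo Imaging Classification and its
pediatric analogue, the Leuven Imaging Classification (LIC). `pedpkd`
implements the full analysis pipeline a pediatric-nephrology study team
needs to run that stratification on a cohort table — plus a synthetic
cohort generator with ground-truth labels so every stage can be validated
without patient data.

## What it computes

- **Volumetry** — per-kidney volume by the stereological (Cavalieri)
  method, `V (ml) = Σ areaᵢ (mm²) × slice thickness (mm) / 1000`, or by
  the ellipsoid approximation `(π/6)·L·W·D`; TKV = left + right;
  htTKV = TKV / height (ml/m). Slice areas come from CSV tables or NIfTI
  label masks.
- **LIC class** — the four age-dependent cutoff curves
  `cutoff_g(age) = A_g · B_g^(age^1.6)` with A = (80, 90, 100, 110) ml/m
  and B = (1.01, 1.012, 1.015, 1.018); htTKV below curve 1 is class A,
  at or above curve 4 class E, with D and E merged (D+E) for group
  statistics.
- **Kidney function** — CKiD-U25 eGFR from serum creatinine and cystatin
  C (combined estimate = mean of both arms); eGFR > 140 ml/min/1.73 m² is
  hyperfiltration, < 90 is CKD staged on KDIGO bands.
- **Hypertension phenotype** — office and 24-h ambulatory BP converted to
  SDS via pluggable LMS normative tables; the ≥ 95th-percentile rule
  (SDS ≥ 1.645) plus medication status yields one of
  {normotensive, white-coat, masked, ambulatory, controlled} with
  masked/ambulatory/controlled counting as hypertensive. Nocturnal
  dipping = 100·(day − night)/day.
- **Cohort summaries** — class-stratified counts and percents
  (half-away-from-zero rounding at the printed precision), median
  (Q1–Q3) tables, Kruskal–Wallis / Mann–Whitney rank tests (exact for
  small tie-free samples) and Fisher exact tests (Fisher–Freeman–Halton
  enumeration for r×c tables) with Bonferroni-adjusted pairwise
  follow-ups.
- **Synthetic cohorts** — seeded generation of patients with known LIC
  class, htTKV inside the correct cutoff band, lens-shaped slice
  profiles that integrate back to the intended volume, analytes
  back-solved from a target eGFR, and class-shifted BP SDS.

## Worked example

```python
from pedpkd.synthetic import generate_cohort
from pedpkd.cohort import derive_all, build_report

cohort, truth, slice_areas = generate_cohort(seed=1)   # 75 patients + 27 controls
derived, errors = derive_all(cohort)                   # volumes -> LIC -> eGFR -> BP
report = build_report(derived)
print(report["lic_classes"])
print(report["ht_prevalence_by_class"])
```

prints (seed 1):

```
{'A': {'n': 32, 'percent': 42.7}, 'B': {'n': 27, 'percent': 36.0},
 'C': {'n': 12, 'percent': 16.0}, 'D+E': {'n': 4, 'percent': 5.3}}
{'A': {'n': 6, 'of': 32, 'percent': 18.8}, 'B': {'n': 9, 'of': 27, 'percent': 33.3},
 'C': {'n': 8, 'of': 12, 'percent': 66.7}, 'D+E': {'n': 4, 'of': 4, 'percent': 100.0}}
```

Each class entry is the number and percent of the 75 patients assigned to
that LIC severity class; the prevalence block shows how hypertension
(masked + ambulatory + controlled) concentrates in the higher-risk
classes — the gradient the class-dependent BP shift of the generator is
built to produce. `derived` also carries per-patient `lic_class`,
`cutoff1..4`, `egfr_combined`, `ckd_stage`, `ht_category`, dipping and
obesity columns.

The same run is available from the shell:

```sh
pedpkd simulate --n 75 --controls 27 --seed 1 --out cohort.csv --areas areas.csv
pedpkd classify --cohort cohort.csv --out classified.csv
pedpkd summarize --cohort cohort.csv --out report.json
pedpkd run --config run.yaml          # end-to-end with provenance manifest
```

## Cohort CSV schema

One row per subject; columns are the flattened record fields
(`patient_id, group, age_years, sex, height_m, weight_kg, weight_sds,
height_sds, bmi_sds, gene, variant_class, biochem.creatinine_mg_dl,
biochem.cystatin_c_mg_l, office.systolic, office.diastolic,
office.systolic_sds, office.diastolic_sds, abpm.map24_sds,
abpm.day_sys_sds, abpm.day_dia_sds, abpm.night_sys_sds,
abpm.night_dia_sds, abpm.day_sys, abpm.day_dia, abpm.night_sys,
abpm.night_dia, meds_flag, volumes.left_ml, volumes.right_ml`). Missing
values are empty cells; "NA" is accepted on read. Slice-area files are
long-format CSV (`patient_id, kidney_side, slice_index, area_mm2[,
thickness_mm]`). Normative BP tables follow
`sex, context, anchor_type, anchor_value, L, M, S, p95`; the packaged
table is synthetic and for testing only — supply real reference data in
the same schema.

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic cohort from the
given seed, runs the complete pipeline (volumetry from slice profiles,
LIC classification, eGFR staging, BP phenotyping, report building),
verifies the derived labels against the generator's ground truth, and
writes its JSON results file:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

See `docs/methods.md` for the models, parameter defaults, numerical
conventions, what the synthetic generator does and does not emulate, and
known limitations.
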