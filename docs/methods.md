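# Methods

## Volumetry

Stereological (Cavalieri) volume treats the kidney as a stack of
contiguous slices: the traced cross-sectional area of each slice (mm²)
times the section thickness (mm), summed and divided by 1000 to give ml.
No gap/overlap modelling is done — the acquisition this targets uses
contiguous 4-mm sections — and the estimator is therefore exactly linear
in thickness and invariant to slice order. Areas can come from a
long-format CSV or from a 3-D integer label mask (NIfTI or array), where
each slice contributes labelled-voxel-count × in-plane voxel area and
the thickness is the between-slice spacing; leading/trailing empty
slices are trimmed. The slicing axis is configurable (default: third
axis), as is the label value (default 1).

The ellipsoid estimate is `(π/6)·length·width·depth/1000` ml. Reported
axis sets carry two maximal lengths (sagittal and coronal) without a
stated convention for which enters the formula; the package defaults to
their arithmetic mean — with the severe-class median axes (129/133 mm
lengths, 63 mm width, 69 mm depth) two such kidneys give 596 ml,
within ~1.5% of the reported 604 ml median ellipsoid TKV — and exposes
`{mean, sagittal, coronal, max}` as a switch. Note medians do not
compose across patients, so this is a plausibility anchor, not an
identity.

TKV is the sum of independently computed per-kidney volumes; unilateral
data are accepted only behind an explicit flag, in which case TKV and
htTKV stay undefined. htTKV = TKV / height with height strictly in
meters (ml/m).

## LIC classification

The four cutoff curves are `cutoff_g(age) = A_g · B_g^(age^1.6)` with
defaults A = (80, 90, 100, 110) ml/m, B = (1.01, 1.012, 1.015, 1.018)
and age exponent 1.6. The expression is parenthesized as
A·(B^(age^1.6)): the cutoffs equal A at age 0 and grow monotonically,
which is the stated behaviour of the model and is consistent with the
published class medians. Because A and B are both strictly increasing
and B ≥ 1, the four curves never cross (asserted numerically over ages
0–25 in the tests).

Class assignment counts the cutoffs at or below the patient's htTKV:
0 → A, …, 4 → E. The boundary convention — a value exactly on a curve —
is not fixed by the model; the package assigns ties to the higher
(more severe) class by default and offers `boundary="lower"` as the
alternative. Age is decimal years at MRI, never rounded. D and E merge
into "D+E" for group statistics. All parameters live in
`LICParameters` / the YAML config so recalibrated curves can be swapped
in; the package does not refit them.

## Kidney function

eGFR uses the CKiD-U25 equations: sex- and age-dependent constants K
applied to `height_m / creatinine` (creatinine arm, mg/dl) and
`1 / cystatin C` (cystatin arm, mg/L), with K varying inside each age
band as `k · growth^(age − pivot)`. The coefficients are not
hard-coded: they ship as a versioned CSV
(`pedpkd/data/u25_coefficients.csv`, bands covering ages 1–25)
transcribed from the primary U25 publication, and any table in the same
schema can be substituted. The combined estimate is the unweighted mean
of the two arms, and a second, independent transcription of the
published constants lives in the test suite as an oracle.

Staging from the combined estimate: strictly above 140 ml/min/1.73 m²
is hyperfiltration, strictly below 90 is CKD (KDIGO stages 2/3/4/5 at
60/30/15 lower bounds), and [90, 140] is normal — the two boundary
values are deliberately inclusive in "normal".

## Blood-pressure phenotyping

Readings are converted to SDS with the LMS transform
`z = ((x/M)^L − 1)/(L·S)` (logarithmic branch at L = 0) against
normative tables keyed by sex, context (office/day/night ×
systolic/diastolic) and an anchor (age or height), with linear
interpolation between anchor rows and no extrapolation outside them.
"Elevated" means at or above the 95th percentile; on the SDS scale the
threshold is the standard-normal quantile 1.6449, applied inclusively.

Office elevation: under 16 years, either component at or above the
sex/age 95th percentile (or SDS ≥ 1.645 when only SDS are available);
from 16 years, the absolute adult rule — systolic ≥ 140 or diastolic
≥ 90 mmHg — applies when raw readings exist. When a cohort supplies SDS
only (as the synthetic generator does), the SDS route is used at every
age; this ignores the ≥ 16-y absolute-threshold refinement, which needs
raw mmHg.

Ambulatory elevation: any of the four day/night × systolic/diastolic
values at or above its 95th percentile. The alternative reading of the
ambulatory definition (requiring both day and night elevation) was
rejected because the complementary normal-profile definition ("all four
below") forces the any-elevated convention.

The phenotype tree: ABPM and office both elevated → ambulatory
hypertension; ABPM only → masked; office only → white-coat; neither,
on antihypertensives → controlled; neither, unmedicated → normotensive.
Elevation patterns take precedence over medication status, since
"controlled" is defined only for normal BP under treatment. Masked,
ambulatory and controlled count as hypertensive. Dipping is
100·(day − night)/day from period means; it is always computed, never
accepted as an input column. 24-h MAP SDS is taken as a device-derived
input and is not reconstructed from systolic/diastolic.

## Cohort statistics

Percentages round half-away-from-zero at a per-cell precision (1
decimal for table percents, 0 for prose-style percents), with
denominators equal to per-variable non-missing n. Continuous variables
are summarized as median (Q1–Q3). Two-group comparisons use
Mann–Whitney U — exact when the combined sample is ≤ 20 and tie-free,
otherwise the normal approximation with tie correction; more than two
groups use Kruskal–Wallis. Categorical tables use Fisher's exact test:
the hypergeometric 2×2 test via scipy, and for r×c tables a
Fisher–Freeman–Halton implementation that enumerates all tables with
the observed margins (validated against R's `fisher.test`); no
installed Python package provides the r×c exact test. Pairwise
follow-ups across the four merged classes are 2×c tests with Bonferroni
multiplier 6 (the number of pairs), capped at 1. Missing data are never
imputed — records are excluded per variable and every exclusion is
logged in the derivation error report.

## Synthetic cohort generator

The generator's defaults state the world the pipeline is built for:
75 patients aged 5–18 plus 27 controls; class mixture equal to the
observed class counts (29, 21, 18, 5, 2)/75; PKD1 fraction 0.893 with
non-missense fractions 0.731 (PKD1) and 0.75 (PKD2); eGFR targets
normal(112, 15) for patients and normal(120, 12) for controls
(truncated to plausible ranges); male fraction 0.56; additive BP-SDS
shifts (0, 0.3, 0.7, 1.2, 1.2) for classes A–E; slice thickness 4 mm
with 12–30 slices per kidney. Per-class medication probabilities are
not reported anywhere; (0.07, 0.08, 0.10, 0.12, 0.12) was chosen once
to give roughly 8% controlled hypertension overall and is not
revisited.

htTKV is drawn uniformly inside the class's cutoff band at the
patient's age, keeping a 2% margin from each boundary (class-A floor
40 ml/m; class-E ceiling 1.6 × the fourth cutoff), so the classifier
recovers the true label with probability 1; uniform-in-band is a
testing convenience, not an inference about real within-class
distributions. A `httkv_noise_sd` option adds multiplicative
measurement error for robustness testing. Heights come from a
deliberately non-physiological toy model
`height = 0.90 + 0.05·age + 0.04·height_sds` (≈1.15–1.95 m over
5–18 y). Slice-area profiles are parabolic (lens-shaped), symmetric and
scaled to integrate exactly to the per-kidney volume. Analytes are
back-solved from the eGFR target so both U25 arms hit it exactly. All
randomness flows through named substreams of a single root seed
(`(seed, crc32(stream name))`), so adding a field never perturbs
existing draws and equal seeds give byte-identical tables.

What a green end-to-end test establishes: the pipeline's algebra and
decision rules are exactly consistent with their definitions. What it
does not establish: robustness to real measurement noise, missingness
patterns, inter-observer tracing variability, non-uniform htTKV
distributions, or correlation structure between BP, genotype and volume
beyond the simple class shifts — real cohorts have all of these.

## Known limitations

- The packaged normative BP table is synthetic; office and ABPM
  phenotyping on raw mmHg requires user-supplied reference tables
  (copyrighted, not redistributable).
- The U25 coefficient bands start at age 1; infants are out of range.
- The r×c exact test enumerates tables and is practical only for the
  small tables cohort summaries produce (hundreds of subjects across a
  handful of cells).
- Cohort-level medians of a real study population are data-dependent
  and are not reproduced by the synthetic world; only structural and
  counting behaviour is.
- The pipeline is cross-sectional: no eGFR slopes, growth curves or
  longitudinal volume trajectories.
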