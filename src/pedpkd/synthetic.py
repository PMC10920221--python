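"""Synthetic pediatric-ADPKD cohorts with ground-truth labels.

The generator emulates the statistical structure the analysis pipeline
assumes — a class mixture over the five LIC severity classes, htTKV drawn
inside the correct cutoff band at each child's age (so class labels are
recoverable exactly), class-dependent upward shifts of BP SDS, a
PKD1-dominated genotype mixture, lens-shaped per-slice area profiles that
the stereology path integrates back to the intended volume, and analytes
back-solved from a target eGFR. Every generated patient carries a truth
record so each pipeline stage can be validated against known labels.

Defaults follow the cohort the package models: 75 patients aged 5-18 and
27 controls, class mixture equal to the observed counts (29, 21, 18, 5, 2)
out of 75, 89.3% PKD1, and mean (SD) eGFR of 112 (15) ml/min/1.73 m^2.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import bp as bp_mod
from . import lic as lic_mod
from . import renal as renal_mod
from .cohort import COHORT_COLUMNS
from .errors import GenerationError, InvalidInputError
from .volumetry import SliceAreaSeries, stereological_volume

#: class mixture = printed class counts (29, 21, 18, 5, 2) / 75
DEFAULT_MIXTURE = (29 / 75, 21 / 75, 18 / 75, 5 / 75, 2 / 75)


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the generator (see the methods note for rationale)."""

    n_patients: int = 75
    n_controls: int = 27
    class_mixture: Tuple[float, ...] = DEFAULT_MIXTURE
    age_range: Tuple[float, float] = (5.0, 18.0)
    male_prob: float = 0.56
    pkd1_prob: float = 0.893
    nonmissense_given_pkd1: float = 0.731
    nonmissense_given_pkd2: float = 0.75
    #: additive BP-SDS shift per class A..E (D and E share the merged shift)
    bp_sds_shift: Tuple[float, ...] = (0.0, 0.3, 0.7, 1.2, 1.2)
    #: antihypertensive-medication probability per class A..E
    meds_prob: Tuple[float, ...] = (0.07, 0.08, 0.10, 0.12, 0.12)
    egfr_mean_sd: Tuple[float, float] = (112.0, 15.0)
    control_egfr_mean_sd: Tuple[float, float] = (120.0, 12.0)
    slice_thickness_mm: float = 4.0
    n_slices_range: Tuple[int, int] = (12, 30)
    #: htTKV band floor for class A and ceiling factor (x cutoff4) for class E
    class_a_floor: float = 40.0
    class_e_ceiling_factor: float = 1.6
    #: fractional margin kept clear of each band boundary
    band_margin: float = 0.02
    #: optional multiplicative noise SD on measured htTKV (0 = exact labels)
    httkv_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise InvalidInputError("class mixture must sum to 1")
        if any(not 0 <= p <= 1 for p in self.class_mixture):
            raise InvalidInputError("mixture probabilities must be in [0, 1]")
        if not self.age_range[0] < self.age_range[1]:
            raise InvalidInputError("age range must be ordered")
        if not 0 <= self.band_margin < 0.5:
            raise InvalidInputError("band margin must be in [0, 0.5)")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated patient."""

    patient_id: str
    true_class: Optional[str]
    true_merged_class: Optional[str]
    true_left_ml: float
    true_right_ml: float
    true_tkv_ml: float
    true_httkv_ml_per_m: float
    true_egfr: float
    true_ht_category: str


def _stream(seed: int, name: str) -> np.random.Generator:
    """A named, independent substream of the root seed.

    Streams are keyed by (seed, crc32(name)) so adding a new draw never
    perturbs existing ones.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def generate_slice_profile(
    target_volume_ml: float,
    n_slices: int,
    thickness_mm: float,
    kidney_side: str = "left",
) -> SliceAreaSeries:
    """A lens-shaped (parabolic) slice-area profile integrating to a target.

    Areas follow a_i proportional to (i+1)(n-i) — symmetric, strictly
    positive, peaked centrally — scaled so that sum(areas) x thickness /
    1000 equals ``target_volume_ml`` up to float rounding.
    """
    if not target_volume_ml > 0:
        raise InvalidInputError("target volume must be > 0")
    if n_slices < 2:
        raise InvalidInputError("need at least two slices")
    if not thickness_mm > 0:
        raise InvalidInputError("thickness must be > 0")
    i = np.arange(n_slices, dtype=float)
    raw = (i + 1.0) * (n_slices - i)
    areas = raw * (target_volume_ml * 1000.0 / (thickness_mm * raw.sum()))
    return SliceAreaSeries(kidney_side=kidney_side, areas_mm2=tuple(areas),
                           slice_thickness_mm=thickness_mm)


def invert_egfr(
    target_egfr: float,
    height_m: float,
    sex: str,
    age_years: float,
    table: Optional[renal_mod.U25CoefficientTable] = None,
) -> Tuple[float, float]:
    """Analytes (creatinine mg/dl, cystatin C mg/L) that give a target eGFR.

    Both single-analyte arms are solved to hit the target exactly, so the
    combined (mean) estimate equals it too.
    """
    if not target_egfr > 0:
        raise InvalidInputError("target eGFR must be > 0")
    if table is None:
        table = renal_mod.U25CoefficientTable.default()
    k_cr = table.k(sex, age_years, "creatinine")
    k_cys = table.k(sex, age_years, "cystatin")
    creatinine = k_cr * height_m / target_egfr
    cystatin = k_cys / target_egfr
    if not (0.05 < creatinine < 15.0 and 0.05 < cystatin < 12.0):
        raise GenerationError(
            f"target eGFR {target_egfr} implies implausible analytes "
            f"(Scr={creatinine:.3g}, cysC={cystatin:.3g})"
        )
    return creatinine, cystatin


def _httkv_band(class_index: int, age: float, config: SynthConfig,
                params: lic_mod.LICParameters) -> Tuple[float, float]:
    cut = [lic_mod.cutoff_curve(g, age, params) for g in (1, 2, 3, 4)]
    edges = [config.class_a_floor] + cut + [config.class_e_ceiling_factor * cut[3]]
    lo, hi = edges[class_index], edges[class_index + 1]
    if not lo < hi:
        raise GenerationError(
            f"infeasible htTKV band for class {lic_mod.LIC_CLASSES[class_index]} at age {age:.2f}"
        )
    return lo, hi


def _toy_height(age: np.ndarray, height_sds: np.ndarray) -> np.ndarray:
    # deliberately simple, non-physiological growth curve; gives ~1.15-1.95 m
    return 0.90 + 0.05 * age + 0.04 * height_sds


_BP_COLS = ("office.systolic_sds", "office.diastolic_sds", "abpm.day_sys_sds",
            "abpm.day_dia_sds", "abpm.night_sys_sds", "abpm.night_dia_sds",
            "abpm.map24_sds")


def generate_cohort(
    config: SynthConfig = SynthConfig(),
    seed: Optional[int] = None,
    lic_params: lic_mod.LICParameters = lic_mod.DEFAULT_PARAMETERS,
    u25_table: Optional[renal_mod.U25CoefficientTable] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[Tuple[str, str], SliceAreaSeries]]:
    """Draw a full synthetic cohort.

    Returns ``(cohort, truth, slice_areas)``: the flat cohort table
    (patients then controls), one truth row per patient/control, and
    per-kidney slice-area series keyed by ``(patient_id, side)`` whose
    stereological volumes equal the tabulated per-kidney volumes.
    """
    if seed is None:
        seed = config.seed
    if u25_table is None:
        u25_table = renal_mod.U25CoefficientTable.default()
    n = config.n_patients
    m = config.n_controls

    classes = _stream(seed, "classes").choice(5, size=n, p=np.asarray(config.class_mixture))
    ages = _stream(seed, "ages").uniform(*config.age_range, size=n)
    height_sds = _stream(seed, "height_sds").standard_normal(n)
    heights = _toy_height(ages, height_sds)
    sexes = np.where(_stream(seed, "sex").uniform(size=n) < config.male_prob, "male", "female")
    u_band = _stream(seed, "httkv").uniform(size=n)
    split = _stream(seed, "split").uniform(0.45, 0.55, size=n)
    n_slices = _stream(seed, "slices").integers(config.n_slices_range[0],
                                                config.n_slices_range[1] + 1, size=(n, 2))
    bp_draw = _stream(seed, "bp").standard_normal((n, len(_BP_COLS)))
    meds_u = _stream(seed, "meds").uniform(size=n)
    egfr_targets = np.clip(
        _stream(seed, "egfr").normal(config.egfr_mean_sd[0], config.egfr_mean_sd[1], size=n),
        35.0, 180.0,
    )
    gene_u = _stream(seed, "gene").uniform(size=n)
    variant_u = _stream(seed, "variant").uniform(size=n)
    weight_sds = _stream(seed, "weight_sds").standard_normal(n) * 0.9 - 0.1
    bmi_sds = _stream(seed, "bmi_sds").standard_normal(n) * 1.1 - 0.3
    dip_sys = _stream(seed, "dip_sys").normal(10.5, 3.0, size=n)
    dip_dia = _stream(seed, "dip_dia").normal(16.0, 4.0, size=n)
    httkv_noise = _stream(seed, "httkv_noise").standard_normal(n)

    rows = []
    truths = []
    slice_areas: Dict[Tuple[str, str], SliceAreaSeries] = {}

    def _one(pid, group, cls_idx, age, sex, height, h_sds, w_sds, b_sds, u, spl,
             ns_pair, bp_vec, meds, target_egfr, gene, variant, d_sys, d_dia, noise):
        if cls_idx is None:
            httkv_true = 95.0 + 35.0 * u  # plausible normal-kidney range
            shift = 0.0
        else:
            lo, hi = _httkv_band(cls_idx, age, config, lic_params)
            margin = config.band_margin * (hi - lo)
            httkv_true = lo + margin + u * (hi - lo - 2 * margin)
            shift = config.bp_sds_shift[cls_idx]
        httkv_meas = httkv_true * (1.0 + config.httkv_noise_sd * noise)
        tkv = httkv_meas * height
        left, right = tkv * spl, tkv * (1 - spl)
        slice_areas[(pid, "left")] = generate_slice_profile(
            left, int(ns_pair[0]), config.slice_thickness_mm, "left")
        slice_areas[(pid, "right")] = generate_slice_profile(
            right, int(ns_pair[1]), config.slice_thickness_mm, "right")

        bp = bp_vec + shift
        creat, cyst = invert_egfr(target_egfr, height, sex, age, u25_table)

        office_elev = bp[0] >= bp_mod.P95_Z or bp[1] >= bp_mod.P95_Z
        abpm_elev = bool(np.any(bp[2:6] >= bp_mod.P95_Z))
        status = bp_mod.classify_ht(bool(office_elev), abpm_elev, bool(meds))

        day_sys = 105.0 + 0.9 * age + 5.0 * bp[2]
        day_dia = 65.0 + 0.4 * age + 4.0 * bp[3]
        night_sys = day_sys * (1 - d_sys / 100.0)
        night_dia = day_dia * (1 - d_dia / 100.0)

        bmi_med = 15.5 + 0.35 * age
        weight = bmi_med * (1 + 0.1 * b_sds) * height ** 2

        row = {c: np.nan for c in COHORT_COLUMNS}
        row.update({
            "patient_id": pid, "group": group, "age_years": age, "sex": sex,
            "height_m": height, "weight_kg": weight, "weight_sds": w_sds,
            "height_sds": h_sds, "bmi_sds": b_sds,
            "gene": gene, "variant_class": variant,
            "biochem.creatinine_mg_dl": creat, "biochem.cystatin_c_mg_l": cyst,
            "office.systolic_sds": bp[0], "office.diastolic_sds": bp[1],
            "abpm.day_sys_sds": bp[2], "abpm.day_dia_sds": bp[3],
            "abpm.night_sys_sds": bp[4], "abpm.night_dia_sds": bp[5],
            "abpm.map24_sds": bp[6],
            "abpm.day_sys": day_sys, "abpm.day_dia": day_dia,
            "abpm.night_sys": night_sys, "abpm.night_dia": night_dia,
            "meds_flag": bool(meds), "volumes.left_ml": left, "volumes.right_ml": right,
        })
        rows.append(row)
        cls = lic_mod.LIC_CLASSES[cls_idx] if cls_idx is not None else None
        truths.append(TruthRecord(
            patient_id=pid, true_class=cls,
            true_merged_class=lic_mod.merge_de(cls) if cls else None,
            true_left_ml=left, true_right_ml=right, true_tkv_ml=tkv,
            true_httkv_ml_per_m=httkv_meas, true_egfr=float(target_egfr),
            true_ht_category=status.category,
        ))

    for i in range(n):
        gene = "PKD1" if gene_u[i] < config.pkd1_prob else "PKD2"
        p_nm = (config.nonmissense_given_pkd1 if gene == "PKD1"
                else config.nonmissense_given_pkd2)
        variant = "non_missense" if variant_u[i] < p_nm else "missense"
        meds = meds_u[i] < config.meds_prob[classes[i]]
        _one(f"P{i + 1:04d}", "adpkd", int(classes[i]), float(ages[i]), str(sexes[i]),
             float(heights[i]), float(height_sds[i]), float(weight_sds[i]),
             float(bmi_sds[i]), float(u_band[i]), float(split[i]), n_slices[i],
             bp_draw[i], meds, float(egfr_targets[i]), gene, variant,
             float(dip_sys[i]), float(dip_dia[i]), float(httkv_noise[i]))

    # controls: healthy children, no genotype, unshifted BP, normal eGFR
    c_ages = _stream(seed, "ctrl_ages").uniform(*config.age_range, size=m)
    c_hsds = _stream(seed, "ctrl_height_sds").standard_normal(m)
    c_heights = _toy_height(c_ages, c_hsds)
    c_sex = np.where(_stream(seed, "ctrl_sex").uniform(size=m) < 0.5, "male", "female")
    c_u = _stream(seed, "ctrl_httkv").uniform(size=m)
    c_split = _stream(seed, "ctrl_split").uniform(0.45, 0.55, size=m)
    c_ns = _stream(seed, "ctrl_slices").integers(config.n_slices_range[0],
                                                 config.n_slices_range[1] + 1, size=(m, 2))
    c_bp = _stream(seed, "ctrl_bp").standard_normal((m, len(_BP_COLS)))
    c_egfr = np.clip(_stream(seed, "ctrl_egfr").normal(
        config.control_egfr_mean_sd[0], config.control_egfr_mean_sd[1], size=m), 60.0, 180.0)
    c_wsds = _stream(seed, "ctrl_weight_sds").standard_normal(m) * 0.9 + 0.3
    c_bsds = _stream(seed, "ctrl_bmi_sds").standard_normal(m) * 1.0 + 0.2
    c_dsys = _stream(seed, "ctrl_dip_sys").normal(10.5, 3.0, size=m)
    c_ddia = _stream(seed, "ctrl_dip_dia").normal(16.0, 4.0, size=m)
    for i in range(m):
        _one(f"C{i + 1:04d}", "control", None, float(c_ages[i]), str(c_sex[i]),
             float(c_heights[i]), float(c_hsds[i]), float(c_wsds[i]), float(c_bsds[i]),
             float(c_u[i]), float(c_split[i]), c_ns[i], c_bp[i], False,
             float(c_egfr[i]), "none", "none", float(c_dsys[i]), float(c_ddia[i]), 0.0)

    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    truth = pd.DataFrame([t.__dict__ for t in truths])
    return cohort, truth, slice_areas


def reference_count_cohort() -> pd.DataFrame:
    """A deterministic 75-patient fixture whose derived labels reproduce a
    fixed set of category counts.

    Marginal composition (labels assigned independently of one another):
    genotype 67 PKD1 (49 non-missense) / 8 PKD2 (6 non-missense); LIC
    classes 29/21/18/5/2 for A/B/C/D/E; hypertension phenotypes 8
    ambulatory, 6 masked, 23 white-coat, 6 controlled, 32 normotensive;
    12 obese; 8 with eGFR below 90 and 6 above 140. All raw inputs are
    constructed so the pipeline's own classification logic recovers these
    counts.
    """
    table = renal_mod.U25CoefficientTable.default()
    params = lic_mod.DEFAULT_PARAMETERS
    age, height, sex = 12.0, 1.50, "male"
    cut = [lic_mod.cutoff_curve(g, age, params) for g in (1, 2, 3, 4)]
    band_mid = {
        "A": 0.5 * (40.0 + cut[0]),
        "B": 0.5 * (cut[0] + cut[1]),
        "C": 0.5 * (cut[1] + cut[2]),
        "D": 0.5 * (cut[2] + cut[3]),
        "E": 1.2 * cut[3],
    }
    class_seq = ["A"] * 29 + ["B"] * 21 + ["C"] * 18 + ["D"] * 5 + ["E"] * 2
    gene_seq = ["PKD1"] * 67 + ["PKD2"] * 8
    variant_seq = (["non_missense"] * 49 + ["missense"] * 18
                   + ["non_missense"] * 6 + ["missense"] * 2)
    # (office_sds, abpm_sds, meds): 8 ambulatory, 6 masked, 23 white-coat,
    # 6 controlled, 32 normotensive
    ht_seq = ([(2.0, 2.0, False)] * 8 + [(0.0, 2.0, False)] * 6
              + [(2.0, 0.0, False)] * 23 + [(0.0, 0.0, True)] * 6
              + [(0.0, 0.0, False)] * 32)
    egfr_seq = [85.0] * 8 + [145.0] * 6 + [110.0] * 61
    bmi_seq = [2.5] * 12 + [0.0] * 63
    sex_seq = ["female"] * 34 + ["male"] * 41

    rows = []
    for i in range(75):
        httkv = band_mid[class_seq[i]]
        tkv = httkv * height
        creat, cyst = invert_egfr(egfr_seq[i], height, sex_seq[i], age, table)
        office_sds, abpm_sds, meds = ht_seq[i]
        row = {c: np.nan for c in COHORT_COLUMNS}
        row.update({
            "patient_id": f"F{i + 1:04d}", "group": "adpkd", "age_years": age,
            "sex": sex_seq[i], "height_m": height, "weight_kg": 40.0,
            "weight_sds": 0.0, "height_sds": 0.0, "bmi_sds": bmi_seq[i],
            "gene": gene_seq[i], "variant_class": variant_seq[i],
            "biochem.creatinine_mg_dl": creat, "biochem.cystatin_c_mg_l": cyst,
            "office.systolic_sds": office_sds, "office.diastolic_sds": office_sds,
            "abpm.day_sys_sds": abpm_sds, "abpm.day_dia_sds": abpm_sds,
            "abpm.night_sys_sds": abpm_sds, "abpm.night_dia_sds": abpm_sds,
            "abpm.map24_sds": 0.0, "meds_flag": meds,
            "volumes.left_ml": tkv / 2, "volumes.right_ml": tkv / 2,
        })
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
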