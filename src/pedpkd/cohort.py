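"""Cohort-level orchestration and class-stratified summaries.

This module turns a flat cohort table (one row per child) into derived
labels — kidney volumes, htTKV, LIC class, eGFR and function stage,
hypertension phenotype, obesity — and produces the stratified summary
tables and nonparametric group comparisons used to describe such cohorts:
counts and percents per stratum, median (Q1-Q3) for continuous variables,
Kruskal-Wallis / Mann-Whitney rank tests, and Fisher exact tests with
Bonferroni-adjusted pairwise follow-ups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import bp as bp_mod
from . import lic as lic_mod
from . import renal as renal_mod
from . import volumetry as vol_mod
from .errors import InvalidInputError

MERGED_CLASSES = lic_mod.MERGED_CLASSES

#: flat cohort-table schema (dot notation for nested fields)
COHORT_COLUMNS = [
    "patient_id", "group", "age_years", "sex", "height_m", "weight_kg",
    "weight_sds", "height_sds", "bmi_sds", "gene", "variant_class",
    "biochem.creatinine_mg_dl", "biochem.cystatin_c_mg_l",
    "office.systolic", "office.diastolic", "office.systolic_sds", "office.diastolic_sds",
    "abpm.map24_sds", "abpm.day_sys_sds", "abpm.day_dia_sds",
    "abpm.night_sys_sds", "abpm.night_dia_sds",
    "abpm.day_sys", "abpm.day_dia", "abpm.night_sys", "abpm.night_dia",
    "meds_flag", "volumes.left_ml", "volumes.right_ml",
]

DERIVED_COLUMNS = [
    "volumes.tkv_ml", "volumes.httkv_ml_per_m",
    "lic_class", "merged_class", "cutoff1", "cutoff2", "cutoff3", "cutoff4",
    "egfr_cr", "egfr_cys", "egfr_combined", "ckd", "ckd_stage", "hyperfiltration",
    "ht_category", "hypertensive", "sys_dipping", "dia_dipping", "obesity_flag",
]

OBESITY_BMI_SDS = 2.0  # BMI-SDS above this flags obesity


class DegenerateGroupWarning(UserWarning):
    """A comparison group holds fewer than two values."""


@dataclass
class ComparisonResult:
    """Outcome of one group comparison."""

    test: str
    statistic: float
    p_value: float
    #: for the two-group rank test: U - n1*n2/2, zero under perfect symmetry
    centered_statistic: Optional[float] = None
    #: (group_i, group_j, statistic, raw_p, bonferroni_p) per pair
    pairwise: List[Tuple[int, int, float, float, float]] = field(default_factory=list)


@dataclass
class GroupSummary:
    """Counts and percents per stratum, plus optional cross-tabulations."""

    by: str
    n_total: int
    counts: Dict[str, int]
    percents: Dict[str, float]
    crosstabs: Dict[str, Dict[str, Dict[str, Tuple[int, float]]]] = field(default_factory=dict)


def _present(value) -> bool:
    if value is None:
        return False
    if isinstance(value, float) and math.isnan(value):
        return False
    return not (isinstance(value, str) and value == "")


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage rounded half-away-from-zero at the given precision."""
    if total <= 0:
        raise InvalidInputError("total must be > 0")
    if not 0 <= count <= total:
        raise InvalidInputError("count must lie in [0, total]")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(value)


def derive_all(
    cohort: pd.DataFrame,
    slice_areas: Optional[dict] = None,
    lic_params: Optional[lic_mod.LICParameters] = None,
    u25_table: Optional[renal_mod.U25CoefficientTable] = None,
    norms: Optional[bp_mod.NormativeTable] = None,
) -> Tuple[pd.DataFrame, List[dict]]:
    """Run every per-patient derivation and return (table, error report).

    Per-record failures never abort the run: each is collected as
    ``{"patient_id", "stage", "error"}`` and the affected derived fields
    stay missing. ``slice_areas`` maps ``(patient_id, side)`` to a
    :class:`~pedpkd.volumetry.SliceAreaSeries`; when present it overrides
    any precomputed per-kidney volumes.
    """
    lic_params = lic_params or lic_mod.DEFAULT_PARAMETERS
    u25_table = u25_table or renal_mod.U25CoefficientTable.default()
    df = cohort.copy()
    for col in DERIVED_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in ("lic_class", "merged_class", "ht_category",
                "ckd", "hyperfiltration", "hypertensive", "obesity_flag"):
        df[col] = df[col].astype(object)
    report: List[dict] = []

    for idx, row in cohort.iterrows():
        pid = row.get("patient_id")

        # --- volumetry ---------------------------------------------------
        try:
            left, right = row.get("volumes.left_ml"), row.get("volumes.right_ml")
            if slice_areas is not None:
                if (pid, "left") in slice_areas:
                    left = vol_mod.stereological_volume(slice_areas[(pid, "left")])
                if (pid, "right") in slice_areas:
                    right = vol_mod.stereological_volume(slice_areas[(pid, "right")])
            if _present(left) and _present(right):
                df.at[idx, "volumes.left_ml"] = left
                df.at[idx, "volumes.right_ml"] = right
                tkv = vol_mod.total_kidney_volume(left, right)
                df.at[idx, "volumes.tkv_ml"] = tkv
                if _present(row.get("height_m")):
                    df.at[idx, "volumes.httkv_ml_per_m"] = vol_mod.height_adjusted_tkv(
                        tkv, row["height_m"]
                    )
                else:
                    report.append({"patient_id": pid, "stage": "volumetry",
                                   "error": "height missing; htTKV not derived"})
        except Exception as exc:  # noqa: BLE001 — collected, not silenced
            report.append({"patient_id": pid, "stage": "volumetry", "error": str(exc)})

        # --- LIC class (patients only) -----------------------------------
        try:
            httkv = df.at[idx, "volumes.httkv_ml_per_m"]
            if row.get("group") == "adpkd" and _present(httkv) and _present(row.get("age_years")):
                res = lic_mod.classify(httkv, row["age_years"], lic_params)
                df.at[idx, "lic_class"] = res.lic_class
                df.at[idx, "merged_class"] = res.merged_class
                for g in range(4):
                    df.at[idx, f"cutoff{g + 1}"] = res.cutoffs_at_age[g]
        except Exception as exc:
            report.append({"patient_id": pid, "stage": "lic", "error": str(exc)})

        # --- kidney function ---------------------------------------------
        try:
            needed = ("biochem.creatinine_mg_dl", "biochem.cystatin_c_mg_l",
                      "height_m", "age_years", "sex")
            if all(_present(row.get(c)) for c in needed):
                panel = renal_mod.BiochemPanel(
                    serum_creatinine_mg_dl=row["biochem.creatinine_mg_dl"],
                    cystatin_c_mg_l=row["biochem.cystatin_c_mg_l"],
                    height_m=row["height_m"],
                    age_years=row["age_years"],
                    sex=row["sex"],
                )
                g = renal_mod.egfr_u25(panel, u25_table)
                df.at[idx, "egfr_cr"] = g.egfr_cr
                df.at[idx, "egfr_cys"] = g.egfr_cys
                df.at[idx, "egfr_combined"] = g.egfr_combined
                df.at[idx, "ckd"] = g.ckd
                df.at[idx, "ckd_stage"] = g.ckd_stage if g.ckd_stage is not None else np.nan
                df.at[idx, "hyperfiltration"] = g.hyperfiltration
        except Exception as exc:
            report.append({"patient_id": pid, "stage": "renal", "error": str(exc)})

        # --- hypertension phenotype --------------------------------------
        try:
            office = bp_mod.OfficeBP(
                systolic=row.get("office.systolic") if _present(row.get("office.systolic")) else None,
                diastolic=row.get("office.diastolic") if _present(row.get("office.diastolic")) else None,
                systolic_sds=row.get("office.systolic_sds") if _present(row.get("office.systolic_sds")) else None,
                diastolic_sds=row.get("office.diastolic_sds") if _present(row.get("office.diastolic_sds")) else None,
                age_years=row.get("age_years") if _present(row.get("age_years")) else None,
                height_m=row.get("height_m") if _present(row.get("height_m")) else None,
                sex=row.get("sex") if _present(row.get("sex")) else None,
            )
            profile = bp_mod.AbpmProfile(
                map24_sds=row.get("abpm.map24_sds") if _present(row.get("abpm.map24_sds")) else None,
                day_sys_sds=row.get("abpm.day_sys_sds") if _present(row.get("abpm.day_sys_sds")) else None,
                day_dia_sds=row.get("abpm.day_dia_sds") if _present(row.get("abpm.day_dia_sds")) else None,
                night_sys_sds=row.get("abpm.night_sys_sds") if _present(row.get("abpm.night_sys_sds")) else None,
                night_dia_sds=row.get("abpm.night_dia_sds") if _present(row.get("abpm.night_dia_sds")) else None,
                day_sys=row.get("abpm.day_sys") if _present(row.get("abpm.day_sys")) else None,
                day_dia=row.get("abpm.day_dia") if _present(row.get("abpm.day_dia")) else None,
                night_sys=row.get("abpm.night_sys") if _present(row.get("abpm.night_sys")) else None,
                night_dia=row.get("abpm.night_dia") if _present(row.get("abpm.night_dia")) else None,
            )
            meds = bool(row.get("meds_flag")) if _present(row.get("meds_flag")) else False
            o_elev = bp_mod.office_elevated(office, norms)
            a_elev = bp_mod.abpm_elevated(profile, norms, sex=office.sex, age_years=office.age_years)
            status = bp_mod.classify_ht(o_elev, a_elev, meds)
            df.at[idx, "ht_category"] = status.category
            df.at[idx, "hypertensive"] = status.hypertensive
            if profile.day_sys is not None:
                df.at[idx, "sys_dipping"] = bp_mod.dipping(profile.day_sys, profile.night_sys)
            if profile.day_dia is not None:
                df.at[idx, "dia_dipping"] = bp_mod.dipping(profile.day_dia, profile.night_dia)
        except Exception as exc:
            report.append({"patient_id": pid, "stage": "bp", "error": str(exc)})

        # --- obesity -------------------------------------------------------
        if _present(row.get("bmi_sds")):
            df.at[idx, "obesity_flag"] = bool(row["bmi_sds"] > OBESITY_BMI_SDS)

    return df, report


def stratified_counts(
    cohort: pd.DataFrame,
    by: str = "merged_class",
    strata: Sequence[str] = MERGED_CLASSES,
    cross: Sequence[str] = (),
    decimals: int = 1,
) -> GroupSummary:
    """Counts and percents per stratum, with optional per-stratum
    cross-tabulations of categorical columns."""
    sub = cohort[cohort[by].notna()]
    n_total = len(sub)
    counts = {s: int((sub[by] == s).sum()) for s in strata}
    if n_total == 0:
        raise InvalidInputError(f"no records carry a value for {by!r}")
    percents = {s: percent(c, n_total, decimals) for s, c in counts.items()}
    crosstabs: Dict[str, Dict[str, Dict[str, Tuple[int, float]]]] = {}
    for col in cross:
        crosstabs[col] = {}
        for s in strata:
            cell = sub[sub[by] == s][col].dropna()
            tab: Dict[str, Tuple[int, float]] = {}
            if len(cell):
                for value, n in cell.value_counts().sort_index().items():
                    tab[str(value)] = (int(n), percent(int(n), len(cell), decimals))
            crosstabs[col][s] = tab
    return GroupSummary(by=by, n_total=n_total, counts=counts, percents=percents,
                        crosstabs=crosstabs)


def compare_continuous(groups: Sequence[Sequence[float]], pairwise: bool = False) -> ComparisonResult:
    """Nonparametric comparison of continuous values across groups.

    Two groups: Mann-Whitney U, exact when the combined sample is <= 20
    and tie-free, otherwise the normal approximation with tie correction.
    More than two: Kruskal-Wallis omnibus test, with optional pairwise
    two-group follow-ups Bonferroni-adjusted by the number of pairs.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InvalidInputError("need at least two groups")
    for g in arrays:
        if g.size == 0:
            raise InvalidInputError("groups must be non-empty")
        if g.size < 2:
            warnings.warn("a comparison group holds fewer than two values",
                          DegenerateGroupWarning, stacklevel=2)

    def two_group(x, y):
        n = x.size + y.size
        pooled = np.concatenate([x, y])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)

    pair_results: List[Tuple[int, int, float, float, float]] = []
    if len(arrays) == 2:
        stat, p = two_group(arrays[0], arrays[1])
        centered = stat - arrays[0].size * arrays[1].size / 2.0
        result = ComparisonResult(test="mann-whitney", statistic=stat, p_value=p,
                                  centered_statistic=centered)
    else:
        stat, p = stats.kruskal(*arrays)
        result = ComparisonResult(test="kruskal-wallis", statistic=float(stat), p_value=float(p))
    if pairwise:
        pairs = list(combinations(range(len(arrays)), 2))
        for i, j in pairs:
            s, praw = two_group(arrays[i], arrays[j])
            pair_results.append((i, j, s, praw, min(1.0, praw * len(pairs))))
        result.pairwise = pair_results
    return result


def _log_factorial(n: int) -> float:
    return math.lgamma(n + 1)


def _ffh_exact(table: np.ndarray) -> float:
    """Fisher-Freeman-Halton exact p for an r x c table.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed one
    (conditional multivariate hypergeometric null).
    """
    t = np.asarray(table, dtype=int)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    const = (sum(_log_factorial(int(r)) for r in rows)
             + sum(_log_factorial(int(c)) for c in cols)
             - _log_factorial(n))

    def log_prob(cells):
        return const - sum(_log_factorial(int(x)) for x in cells)

    obs_lp = log_prob(t.ravel())
    r, c = t.shape
    total = 0.0

    def fill_row(i: int, col_rem, acc):
        nonlocal total
        if i == r - 1:
            cells = acc + list(col_rem)
            lp = log_prob(cells)
            if lp <= obs_lp + 1e-7:
                total += math.exp(lp)
            return
        target = int(rows[i])

        def compose(j: int, rem: int, cur):
            if j == c - 1:
                if rem <= col_rem[j]:
                    new_rem = list(col_rem)
                    for k_, v in enumerate(cur):
                        new_rem[k_] -= v
                    new_rem[j] -= rem
                    fill_row(i + 1, new_rem, acc + cur + [rem])
                return
            for v in range(min(rem, col_rem[j]) + 1):
                compose(j + 1, rem - v, cur + [v])

        compose(0, target, [])

    fill_row(0, list(int(x) for x in cols), [])
    return min(1.0, total)


def compare_categorical(table, pairwise: bool = False) -> ComparisonResult:
    """Fisher exact test on an r x c count table.

    2 x 2 tables use the hypergeometric two-sided test; larger tables the
    Fisher-Freeman-Halton generalization by full enumeration (feasible for
    the small tables cohort summaries produce). Pairwise follow-ups test
    every pair of rows as a 2 x c table with Bonferroni adjustment.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2:
        raise InvalidInputError("count table must be 2-D")
    if np.any(t < 0):
        raise InvalidInputError("counts must be non-negative")
    if t.sum() == 0:
        raise InvalidInputError("count table is all zero")

    def one_test(tab: np.ndarray) -> float:
        tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            return 1.0
        if tab.shape == (2, 2):
            return float(stats.fisher_exact(tab, alternative="two-sided")[1])
        return _ffh_exact(tab)

    p = one_test(t)
    result = ComparisonResult(test="fisher-exact", statistic=float("nan"), p_value=p)
    if pairwise:
        pairs = list(combinations(range(t.shape[0]), 2))
        out = []
        for i, j in pairs:
            praw = one_test(t[[i, j], :])
            out.append((i, j, float("nan"), praw, min(1.0, praw * len(pairs))))
        result.pairwise = out
    return result


def _median_q1_q3(values: pd.Series) -> Optional[dict]:
    v = values.dropna().to_numpy(dtype=float)
    if v.size == 0:
        return None
    return {
        "n": int(v.size),
        "median": float(np.median(v)),
        "q1": float(np.percentile(v, 25)),
        "q3": float(np.percentile(v, 75)),
    }


#: continuous variables summarized per class in the standard report
REPORT_CONTINUOUS = [
    "age_years", "weight_sds", "height_sds", "bmi_sds", "egfr_combined",
    "volumes.tkv_ml", "volumes.httkv_ml_per_m",
    "office.systolic_sds", "office.diastolic_sds", "abpm.map24_sds",
    "abpm.day_sys_sds", "abpm.day_dia_sds", "abpm.night_sys_sds",
    "abpm.night_dia_sds", "sys_dipping", "dia_dipping",
]


def build_report(cohort: pd.DataFrame, decimals: int = 1) -> dict:
    """Machine-readable cohort summary (class-stratified) as a JSON-safe dict.

    Includes whole-cohort composition (genotype, kidney function,
    hypertension phenotypes, obesity), per-class counts and percents,
    per-class median (Q1-Q3) for the standard continuous variables with a
    Kruskal-Wallis p-value, hypertension prevalence per class, and a
    Fisher exact test of genotype by class. Deterministic given the data:
    permuting record order leaves the report unchanged.
    """
    patients = cohort[cohort["group"] == "adpkd"] if "group" in cohort.columns else cohort
    n = len(patients)
    if n == 0:
        raise InvalidInputError("cohort holds no patient records")
    controls = cohort[cohort["group"] == "control"] if "group" in cohort.columns else cohort.iloc[0:0]

    report: dict = {"n_patients": n, "n_controls": int(len(controls))}

    # genotype composition
    gene = patients["gene"].dropna()
    gen: dict = {}
    for g in ("PKD1", "PKD2"):
        ng = int((gene == g).sum())
        gen[g] = {"n": ng, "percent": percent(ng, len(gene), decimals) if len(gene) else None}
        within = patients[(patients["gene"] == g) & patients["variant_class"].notna()]
        if len(within):
            nm = int((within["variant_class"] == "non_missense").sum())
            gen[f"non_missense_within_{g}"] = {"n": nm, "percent": percent(nm, len(within), decimals)}
    report["genotype"] = gen

    # LIC class composition and cross-tabs
    summary = stratified_counts(
        patients, by="merged_class", strata=MERGED_CLASSES,
        cross=("gene", "variant_class", "ht_category"), decimals=decimals,
    )
    report["lic_classes"] = {
        s: {"n": summary.counts[s], "percent": summary.percents[s]} for s in MERGED_CLASSES
    }
    report["lic_crosstabs"] = summary.crosstabs

    # kidney function
    egfr = patients["egfr_combined"].dropna()
    kf: dict = {}
    if len(egfr):
        n_ckd = int((egfr < renal_mod.CKD_THRESHOLD).sum())
        n_hyp = int((egfr > renal_mod.HYPERFILTRATION_THRESHOLD).sum())
        kf["ckd"] = {"n": n_ckd, "percent": percent(n_ckd, len(egfr), decimals)}
        kf["hyperfiltration"] = {"n": n_hyp, "percent": percent(n_hyp, len(egfr), decimals)}
    report["kidney_function"] = kf

    # hypertension phenotypes
    ht = patients["ht_category"].dropna()
    htc: dict = {}
    for cat in bp_mod.HT_CATEGORIES:
        nc = int((ht == cat).sum())
        htc[cat] = {"n": nc, "percent": percent(nc, len(ht), decimals) if len(ht) else None}
    if len(ht):
        n_ht = int((patients["hypertensive"] == True).sum())  # noqa: E712 — NaN-safe
        htc["overall_hypertensive"] = {"n": n_ht, "percent": percent(n_ht, len(ht), 0)}
    report["hypertension"] = htc

    # obesity
    ob = patients["obesity_flag"].dropna()
    if len(ob):
        n_ob = int(ob.astype(bool).sum())
        report["obesity"] = {"n": n_ob, "percent": percent(n_ob, len(ob), 0)}

    # hypertension prevalence per class
    prev: dict = {}
    for s in MERGED_CLASSES:
        cls = patients[(patients["merged_class"] == s) & patients["hypertensive"].notna()]
        if len(cls):
            n_ht = int(cls["hypertensive"].astype(bool).sum())
            prev[s] = {"n": n_ht, "of": len(cls), "percent": percent(n_ht, len(cls), decimals)}
    report["ht_prevalence_by_class"] = prev

    # continuous variables by class with omnibus rank test
    cont: dict = {}
    for col in REPORT_CONTINUOUS:
        if col not in patients.columns:
            continue
        per_class: dict = {}
        groups = []
        for s in MERGED_CLASSES:
            cell = _median_q1_q3(patients[patients["merged_class"] == s][col])
            per_class[s] = cell
            if cell is not None and cell["n"] >= 2:
                groups.append(patients[patients["merged_class"] == s][col].dropna().to_numpy())
        entry: dict = {"by_class": per_class}
        pooled = np.concatenate(groups) if groups else np.array([])
        if len(groups) >= 2 and np.unique(pooled).size >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegenerateGroupWarning)
                cmp_res = compare_continuous(groups)
            entry["test"] = cmp_res.test
            entry["p_value"] = cmp_res.p_value
        cont[col] = entry
    report["continuous_by_class"] = cont

    # genotype x class exact test
    classes_present = [s for s in MERGED_CLASSES if summary.counts[s] > 0]
    if len(classes_present) >= 2 and len(gene):
        tab = np.array([
            [int(((patients["merged_class"] == s) & (patients["gene"] == g)).sum())
             for g in ("PKD1", "PKD2")]
            for s in classes_present
        ])
        if tab.sum() > 0:
            res = compare_categorical(tab, pairwise=False)
            report["gene_by_class"] = {"test": res.test, "p_value": res.p_value}

    return report


def plot_ht_prevalence(report: dict, ax=None):
    """Bar chart of hypertension prevalence per merged LIC class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    prev = report.get("ht_prevalence_by_class", {})
    labels = [s for s in MERGED_CLASSES if s in prev]
    values = [prev[s]["percent"] for s in labels]
    ax.bar(labels, values, color="#3465a4")
    ax.set_ylabel("hypertension prevalence (%)")
    ax.set_xlabel("LIC class")
    ax.set_ylim(0, max(values + [10]) * 1.2)
    return ax
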