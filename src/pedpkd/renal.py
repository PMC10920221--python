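"""Pediatric kidney-function assessment (CKiD-U25 eGFR and staging).

eGFR (ml/min/1.73 m^2) is estimated from serum creatinine and cystatin C
with the CKiD-U25 equations, which use sex- and age-dependent multiplicative
constants K applied to simple analyte kernels:

    eGFR_cr  = K_cr(sex, age)  * height_m / Scr         (Scr in mg/dl)
    eGFR_cys = K_cys(sex, age) / cystatin_C             (cystatin C in mg/L)

with K varying smoothly inside each age band as k * growth**(age - pivot).
The combined estimate is the unweighted mean of the two arms. The
coefficients are not hard-coded: they live in a versioned CSV shipped with
the package and can be overridden with any table following the same schema.

Function staging uses the combined estimate: above 140 is hyperfiltration
(an early compensatory state common in pediatric ADPKD), below 90 is
chronic kidney disease staged on the usual KDIGO bands, and [90, 140] is
normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Optional

import pandas as pd

from .errors import ConfigurationError, InvalidInputError

SEXES = ("male", "female")
ANALYTES = ("creatinine", "cystatin")

HYPERFILTRATION_THRESHOLD = 140.0  # ml/min/1.73 m^2, strictly above
CKD_THRESHOLD = 90.0  # strictly below

#: KDIGO GFR stages for eGFR < 90: (lower bound inclusive, stage)
_KDIGO_BANDS = ((60.0, 2), (30.0, 3), (15.0, 4), (0.0, 5))


@dataclass(frozen=True)
class BiochemPanel:
    """Analytes and anthropometrics needed for a U25 eGFR."""

    serum_creatinine_mg_dl: float
    cystatin_c_mg_l: float
    height_m: float
    age_years: float
    sex: str

    def __post_init__(self):
        if self.sex not in SEXES:
            raise InvalidInputError(f"sex must be one of {SEXES}")
        if not self.serum_creatinine_mg_dl > 0:
            raise InvalidInputError("serum creatinine must be > 0 mg/dl")
        if not self.cystatin_c_mg_l > 0:
            raise InvalidInputError("cystatin C must be > 0 mg/L")
        if not 0 < self.height_m < 2.5:
            raise InvalidInputError("height must be in (0, 2.5) m")
        if not 0 <= self.age_years < 25:
            raise InvalidInputError("U25 equations cover ages [0, 25) years")


class U25CoefficientTable:
    """Sex x age-band x analyte coefficient lookup.

    Schema (CSV): sex, age_low, age_high, analyte, k, growth, pivot_age.
    Bands are half-open [age_low, age_high) and must not overlap within a
    (sex, analyte) pair. K(age) = k * growth**(age - pivot_age).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sex", "age_low", "age_high", "analyte", "k", "growth", "pivot_age"}
        missing = required - set(frame.columns)
        if missing:
            raise ConfigurationError(f"coefficient table missing columns: {sorted(missing)}")
        bad_sex = set(frame["sex"]) - set(SEXES)
        bad_analyte = set(frame["analyte"]) - set(ANALYTES)
        if bad_sex or bad_analyte:
            raise ConfigurationError(
                f"unknown sex values {sorted(bad_sex)} or analytes {sorted(bad_analyte)}"
            )
        if (frame["k"] <= 0).any() or (frame["growth"] <= 0).any():
            raise ConfigurationError("k and growth must be positive")
        for (_, _), sub in frame.groupby(["sex", "analyte"]):
            bands = sorted(zip(sub["age_low"], sub["age_high"]))
            for (l1, h1), (l2, _) in zip(bands, bands[1:]):
                if l2 < h1:
                    raise ConfigurationError("age bands overlap")
        self._frame = frame.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @classmethod
    def from_csv(cls, path) -> "U25CoefficientTable":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def default(cls) -> "U25CoefficientTable":
        """The packaged CKiD-U25 coefficients."""
        with resources.files("pedpkd.data").joinpath("u25_coefficients.csv").open() as fh:
            return cls(pd.read_csv(fh, comment="#"))

    def k(self, sex: str, age_years: float, analyte: str) -> float:
        """The multiplicative constant K for this sex/age/analyte."""
        sub = self._frame
        row = sub[
            (sub["sex"] == sex)
            & (sub["analyte"] == analyte)
            & (sub["age_low"] <= age_years)
            & (age_years < sub["age_high"])
        ]
        if len(row) == 0:
            raise ConfigurationError(
                f"no {analyte} coefficient row for sex={sex!r}, age={age_years}"
            )
        r = row.iloc[0]
        return float(r["k"] * r["growth"] ** (age_years - r["pivot_age"]))


class GFRResult(NamedTuple):
    """Single-analyte and combined eGFR plus derived function flags."""

    egfr_cr: float
    egfr_cys: float
    egfr_combined: float
    ckd: bool
    ckd_stage: Optional[int]
    hyperfiltration: bool


class KidneyFunction(NamedTuple):
    category: str  # hyperfiltration | normal | ckd
    ckd: bool
    ckd_stage: Optional[int]
    hyperfiltration: bool


def egfr_u25(panel: BiochemPanel, table: Optional[U25CoefficientTable] = None) -> GFRResult:
    """CKiD-U25 eGFR from a biochemistry panel.

    Returns the creatinine-based, cystatin-based and combined (mean)
    estimates together with CKD/hyperfiltration flags derived from the
    combined estimate.
    """
    if table is None:
        table = U25CoefficientTable.default()
    k_cr = table.k(panel.sex, panel.age_years, "creatinine")
    k_cys = table.k(panel.sex, panel.age_years, "cystatin")
    egfr_cr = k_cr * panel.height_m / panel.serum_creatinine_mg_dl
    egfr_cys = k_cys / panel.cystatin_c_mg_l
    combined = 0.5 * (egfr_cr + egfr_cys)
    fn = classify_kidney_function(combined)
    return GFRResult(
        egfr_cr=egfr_cr,
        egfr_cys=egfr_cys,
        egfr_combined=combined,
        ckd=fn.ckd,
        ckd_stage=fn.ckd_stage,
        hyperfiltration=fn.hyperfiltration,
    )


def classify_kidney_function(egfr_combined: float) -> KidneyFunction:
    """Stage kidney function from a combined eGFR.

    Strictly above 140 is hyperfiltration; strictly below 90 is CKD with
    KDIGO stages 2 (60-89), 3 (30-59), 4 (15-29), 5 (<15); 90 and 140 are
    both "normal".
    """
    if not (math.isfinite(egfr_combined) and egfr_combined > 0):
        raise InvalidInputError("eGFR must be finite and > 0")
    if egfr_combined > HYPERFILTRATION_THRESHOLD:
        return KidneyFunction("hyperfiltration", False, None, True)
    if egfr_combined >= CKD_THRESHOLD:
        return KidneyFunction("normal", False, None, False)
    for lower, stage in _KDIGO_BANDS:
        if egfr_combined >= lower:
            return KidneyFunction("ckd", True, stage, False)
    raise AssertionError("unreachable")
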