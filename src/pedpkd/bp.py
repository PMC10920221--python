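"""Blood-pressure phenotyping: SDS conversion, thresholds, and the
office/ambulatory hypertension decision tree.

Raw office and ambulatory (ABPM) readings are converted to standard
deviation scores (SDS, z-scores) against pluggable normative tables using
the LMS transform; 'elevated' means at or above the sex-specific 95th
percentile (equivalently SDS >= 1.645 on the z scale). Combining the
office flag, the ABPM flag and antihypertensive-medication status yields
one of five mutually exclusive phenotypes:

========== ==========  ====  ===============
office     ambulatory  meds  category
========== ==========  ====  ===============
elevated   elevated    any   ambulatory_ht
normal     elevated    any   masked
elevated   normal      any   white_coat
normal     normal      yes   controlled_ht
normal     normal      no    normotensive
========== ==========  ====  ===============

A child is counted hypertensive when the category is ambulatory, masked
or controlled hypertension (white-coat alone is not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .errors import (
    IncompleteProfileError,
    InvalidInputError,
    OutOfRangeError,
)

#: standard-normal 95th-percentile quantile: SDS at the p95 threshold
P95_Z = 1.6448536269514722

#: absolute office threshold for adolescents >= 16 y, mmHg (systolic, diastolic)
ADULT_OFFICE_THRESHOLD = (140.0, 90.0)
ADULT_OFFICE_AGE = 16.0

HT_CATEGORIES = ("normotensive", "white_coat", "masked", "ambulatory_ht", "controlled_ht")
HYPERTENSIVE_CATEGORIES = frozenset({"masked", "ambulatory_ht", "controlled_ht"})

BP_CONTEXTS = ("office_sys", "office_dia", "day_sys", "day_dia", "night_sys", "night_dia")


def lms_z(value: float, L: float, M: float, S: float) -> float:
    """The LMS (Box-Cox) z-score: ((x/M)^L - 1) / (L*S), or ln(x/M)/S at L=0."""
    if not (value > 0 and M > 0 and S > 0):
        raise InvalidInputError("LMS transform needs value, M and S all > 0")
    if L == 0.0:
        return math.log(value / M) / S
    return ((value / M) ** L - 1.0) / (L * S)


def bp_sds(value_mmHg: float, normative_row) -> float:
    """SDS of one reading against a normative (L, M, S) row.

    ``normative_row`` is any object with L/M/S attributes or a 3-sequence.
    """
    if hasattr(normative_row, "L"):
        L, M, S = normative_row.L, normative_row.M, normative_row.S
    else:
        L, M, S = normative_row
    return lms_z(value_mmHg, L, M, S)


def lms_quantile(z: float, L: float, M: float, S: float) -> float:
    """Inverse LMS transform: the value at a given z-score."""
    if L == 0.0:
        return M * math.exp(z * S)
    return M * (1.0 + L * S * z) ** (1.0 / L)


class NormativeTable:
    """Normative BP reference keyed by sex, context and an anchor variable.

    Schema (CSV): sex, context, anchor_type, anchor_value, L, M, S, p95.
    ``context`` is one of ``office_sys/office_dia/day_sys/day_dia/
    night_sys/night_dia``; the anchor is age (years) or height. L, M, S
    are interpolated linearly between anchor rows; anchors outside the
    tabulated range raise :class:`OutOfRangeError` (no extrapolation).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sex", "context", "anchor_type", "anchor_value", "L", "M", "S"}
        missing = required - set(frame.columns)
        if missing:
            raise InvalidInputError(f"normative table missing columns: {sorted(missing)}")
        if (frame["M"] <= 0).any() or (frame["S"] <= 0).any():
            raise InvalidInputError("M and S must be positive")
        frame = frame.sort_values(["sex", "context", "anchor_value"]).reset_index(drop=True)
        for (_, _), sub in frame.groupby(["sex", "context"]):
            anchors = sub["anchor_value"].to_numpy()
            if np.any(np.diff(anchors) <= 0):
                raise InvalidInputError("anchor values must be strictly increasing per key")
        self._frame = frame

    @classmethod
    def from_csv(cls, path) -> "NormativeTable":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def synthetic_default(cls) -> "NormativeTable":
        """A packaged, clearly synthetic table (testing only — not real
        pediatric reference data)."""
        with resources.files("pedpkd.data").joinpath("synthetic_bp_norms.csv").open() as fh:
            return cls(pd.read_csv(fh, comment="#"))

    def _interp(self, sex: str, context: str, anchor_value: float):
        sub = self._frame[(self._frame["sex"] == sex) & (self._frame["context"] == context)]
        if len(sub) == 0:
            raise OutOfRangeError(f"no normative rows for sex={sex!r}, context={context!r}")
        anchors = sub["anchor_value"].to_numpy(dtype=float)
        if not anchors[0] <= anchor_value <= anchors[-1]:
            raise OutOfRangeError(
                f"anchor {anchor_value} outside normative range "
                f"[{anchors[0]}, {anchors[-1]}] for {sex}/{context}"
            )
        out = []
        for col in ("L", "M", "S"):
            out.append(float(np.interp(anchor_value, anchors, sub[col].to_numpy(dtype=float))))
        return tuple(out)

    def sds(self, value: float, sex: str, context: str, anchor_value: float) -> float:
        """SDS of a reading via the LMS transform at the interpolated anchor."""
        L, M, S = self._interp(sex, context, anchor_value)
        return lms_z(value, L, M, S)

    def p95(self, sex: str, context: str, anchor_value: float) -> float:
        """The 95th percentile value. Uses a tabulated ``p95`` column when
        present, otherwise the LMS quantile at z = 1.645."""
        sub = self._frame[(self._frame["sex"] == sex) & (self._frame["context"] == context)]
        if "p95" in sub.columns and sub["p95"].notna().all() and len(sub) > 0:
            anchors = sub["anchor_value"].to_numpy(dtype=float)
            if not (len(anchors) and anchors[0] <= anchor_value <= anchors[-1]):
                raise OutOfRangeError(f"anchor {anchor_value} outside normative range")
            return float(np.interp(anchor_value, anchors, sub["p95"].to_numpy(dtype=float)))
        L, M, S = self._interp(sex, context, anchor_value)
        return lms_quantile(P95_Z, L, M, S)


@dataclass(frozen=True)
class OfficeBP:
    """Averaged office readings (mean of three) and/or their SDS."""

    systolic: Optional[float] = None
    diastolic: Optional[float] = None
    systolic_sds: Optional[float] = None
    diastolic_sds: Optional[float] = None
    age_years: Optional[float] = None
    height_m: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self):
        for v in (self.systolic, self.diastolic):
            if v is not None and not 30 < v < 250:
                raise InvalidInputError(f"implausible office BP {v} mmHg")


@dataclass(frozen=True)
class AbpmProfile:
    """ABPM summary: day/night systolic & diastolic means and/or SDS, plus
    the 24-h mean arterial pressure SDS. Dipping is computed from the
    means (never supplied directly)."""

    map24_sds: Optional[float] = None
    day_sys_sds: Optional[float] = None
    day_dia_sds: Optional[float] = None
    night_sys_sds: Optional[float] = None
    night_dia_sds: Optional[float] = None
    day_sys: Optional[float] = None
    day_dia: Optional[float] = None
    night_sys: Optional[float] = None
    night_dia: Optional[float] = None

    def __post_init__(self):
        # day and night means only make sense together
        means = (self.day_sys, self.night_sys)
        if (means[0] is None) != (means[1] is None):
            raise InvalidInputError("day and night systolic means must be present together")
        means = (self.day_dia, self.night_dia)
        if (means[0] is None) != (means[1] is None):
            raise InvalidInputError("day and night diastolic means must be present together")


class HTStatus(NamedTuple):
    category: str
    hypertensive: bool


def office_elevated(office: OfficeBP, table: Optional[NormativeTable] = None) -> bool:
    """Whether office BP is elevated.

    Children under 16 are compared with the sex/age 95th percentile (raw
    mmHg route, requiring a normative table) or with SDS >= 1.645 when
    only SDS are available. From age 16 the absolute adult threshold
    140/90 mmHg applies when raw readings exist; otherwise the SDS route
    is used as a fallback.
    """
    raw = office.systolic is not None and office.diastolic is not None
    if raw and office.age_years is not None and office.age_years >= ADULT_OFFICE_AGE:
        return office.systolic >= ADULT_OFFICE_THRESHOLD[0] or office.diastolic >= ADULT_OFFICE_THRESHOLD[1]
    if raw and table is not None:
        if office.sex is None or office.age_years is None:
            raise InvalidInputError("sex and age are required for the normative office route")
        p95_sys = table.p95(office.sex, "office_sys", office.age_years)
        p95_dia = table.p95(office.sex, "office_dia", office.age_years)
        return office.systolic >= p95_sys or office.diastolic >= p95_dia
    if office.systolic_sds is not None and office.diastolic_sds is not None:
        return office.systolic_sds >= P95_Z or office.diastolic_sds >= P95_Z
    if raw:
        raise OutOfRangeError("raw office BP given but no normative table supplied")
    raise IncompleteProfileError("office BP needs either raw readings or both SDS values")


def abpm_elevated(profile: AbpmProfile, table: Optional[NormativeTable] = None,
                  sex: Optional[str] = None, age_years: Optional[float] = None) -> bool:
    """Whether the ambulatory profile is elevated.

    True when any of the four period x component values (day/night,
    systolic/diastolic) is at or above its 95th percentile — equivalently
    SDS >= 1.645. A profile is normal only when all four are below.
    """
    sds = (profile.day_sys_sds, profile.day_dia_sds, profile.night_sys_sds, profile.night_dia_sds)
    if all(v is not None for v in sds):
        return any(v >= P95_Z for v in sds)
    means = (profile.day_sys, profile.day_dia, profile.night_sys, profile.night_dia)
    if all(v is not None for v in means):
        if table is None or sex is None or age_years is None:
            raise OutOfRangeError("raw ABPM means need a normative table plus sex and age")
        contexts = ("day_sys", "day_dia", "night_sys", "night_dia")
        return any(v >= table.p95(sex, c, age_years) for v, c in zip(means, contexts))
    raise IncompleteProfileError(
        "ABPM profile must carry all four day/night sys/dia values (SDS or means)"
    )


def dipping(day_mean: float, night_mean: float) -> float:
    """Nocturnal dipping, percent: 100 * (day - night) / day."""
    if not (math.isfinite(day_mean) and day_mean > 0):
        raise InvalidInputError("daytime mean must be > 0")
    return 100.0 * (day_mean - night_mean) / day_mean


def classify_ht(office_elev: bool, abpm_elev: bool, on_antihypertensives: bool) -> HTStatus:
    """The five-way hypertension phenotype from the three resolved flags.

    Elevation patterns take precedence over medication status: a medicated
    child with elevated readings is classified by the pattern, and
    "controlled" is reserved for normal BP under treatment.
    """
    if abpm_elev and office_elev:
        category = "ambulatory_ht"
    elif abpm_elev:
        category = "masked"
    elif office_elev:
        category = "white_coat"
    elif on_antihypertensives:
        category = "controlled_ht"
    else:
        category = "normotensive"
    return HTStatus(category=category, hypertensive=category in HYPERTENSIVE_CATEGORIES)
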