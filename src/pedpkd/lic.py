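"""Leuven Imaging Classification (LIC) for pediatric ADPKD.

The LIC stratifies children with ADPKD into severity classes A-E by
comparing their height-adjusted total kidney volume (htTKV, ml/m) with
four age-dependent cutoff curves

    cutoff_g(age) = A_g * B_g ** (age ** 1.6),   g = 1..4

with A = (80, 90, 100, 110) ml/m and B = (1.01, 1.012, 1.015, 1.018).
At birth the cutoffs equal A; they grow super-linearly with age because
B > 1 and the age exponent exceeds 1. htTKV below the first curve is
class A; at or above the fourth curve is class E. Classes D and E are
conventionally merged (D+E) for group statistics because few children
reach them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .errors import InvalidInputError

LIC_CLASSES = ("A", "B", "C", "D", "E")
MERGED_CLASSES = ("A", "B", "C", "D+E")


@dataclass(frozen=True)
class LICParameters:
    """Coefficients of the four cutoff curves.

    A : base cutoffs at age 0, ml/m, strictly increasing.
    B : growth bases, dimensionless, each >= 1, strictly increasing.
    age_exponent : exponent applied to age (years) before exponentiation.
    boundary : "upper" assigns an htTKV exactly on a cutoff to the higher
        (more severe) class; "lower" to the lower class. A measure-zero
        convention, configurable because the model itself does not fix it.
    """

    A: Tuple[float, float, float, float] = (80.0, 90.0, 100.0, 110.0)
    B: Tuple[float, float, float, float] = (1.01, 1.012, 1.015, 1.018)
    age_exponent: float = 1.6
    boundary: str = "upper"

    def __post_init__(self):
        object.__setattr__(self, "A", tuple(float(a) for a in self.A))
        object.__setattr__(self, "B", tuple(float(b) for b in self.B))
        if len(self.A) != 4 or len(self.B) != 4:
            raise InvalidInputError("A and B must each hold four coefficients")
        if any(a2 <= a1 for a1, a2 in zip(self.A, self.A[1:])):
            raise InvalidInputError("A coefficients must be strictly increasing")
        if any(b2 <= b1 for b1, b2 in zip(self.B, self.B[1:])):
            raise InvalidInputError("B coefficients must be strictly increasing")
        if any(b < 1.0 for b in self.B):
            raise InvalidInputError("each B must be >= 1")
        if not self.age_exponent > 0:
            raise InvalidInputError("age_exponent must be > 0")
        if self.boundary not in ("upper", "lower"):
            raise InvalidInputError('boundary must be "upper" or "lower"')


DEFAULT_PARAMETERS = LICParameters()


@dataclass(frozen=True)
class LICResult:
    """Class assignment for one patient at one age."""

    lic_class: str
    merged_class: str
    cutoffs_at_age: Tuple[float, float, float, float]
    httkv_ml_per_m: float
    age_years: float


def cutoff_curve(grade_index: int, age_years: float, params: LICParameters = DEFAULT_PARAMETERS) -> float:
    """Evaluate cutoff curve ``grade_index`` (1..4) at a decimal age in years."""
    if grade_index not in (1, 2, 3, 4):
        raise InvalidInputError("grade_index must be 1..4")
    if not (math.isfinite(age_years) and age_years >= 0):
        raise InvalidInputError("age must be finite and >= 0")
    a = params.A[grade_index - 1]
    b = params.B[grade_index - 1]
    return a * b ** (age_years ** params.age_exponent)


def cutoffs_at_age(age_years, params: LICParameters = DEFAULT_PARAMETERS) -> np.ndarray:
    """All four cutoffs at one age (or a vector of ages; result shape (..., 4))."""
    age = np.asarray(age_years, dtype=float)
    if np.any(~np.isfinite(age)) or np.any(age < 0):
        raise InvalidInputError("ages must be finite and >= 0")
    A = np.asarray(params.A)
    B = np.asarray(params.B)
    return A * B ** (age[..., None] ** params.age_exponent)


def classify(
    httkv_ml_per_m: float,
    age_years: float,
    params: LICParameters = DEFAULT_PARAMETERS,
) -> LICResult:
    """Assign the LIC class for an htTKV at a given age.

    The class index is the number of cutoff curves lying at or below the
    htTKV (with the default "upper" boundary convention; "lower" counts
    strictly-below curves), so htTKV below the first cutoff is class A and
    at or above the fourth is class E.
    """
    if not (math.isfinite(httkv_ml_per_m) and httkv_ml_per_m >= 0):
        raise InvalidInputError("htTKV must be finite and >= 0")
    cutoffs = tuple(cutoff_curve(g, age_years, params) for g in (1, 2, 3, 4))
    if params.boundary == "upper":
        idx = sum(c <= httkv_ml_per_m for c in cutoffs)
    else:
        idx = sum(c < httkv_ml_per_m for c in cutoffs)
    lic_class = LIC_CLASSES[idx]
    return LICResult(
        lic_class=lic_class,
        merged_class=merge_de(lic_class),
        cutoffs_at_age=cutoffs,
        httkv_ml_per_m=float(httkv_ml_per_m),
        age_years=float(age_years),
    )


def merge_de(lic_class: str) -> str:
    """Collapse classes D and E into the combined stratum "D+E"."""
    if lic_class not in LIC_CLASSES:
        raise InvalidInputError(f"unknown LIC class {lic_class!r}")
    return "D+E" if lic_class in ("D", "E") else lic_class
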