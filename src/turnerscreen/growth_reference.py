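"""LMS-method growth references and z-score conversion.

The LMS method summarises an anthropometric reference distribution at each
age by three quantities: a Box-Cox power ``L`` that removes skewness, the
median ``M``, and the coefficient of variation ``S``.  A measurement ``x``
at a given age converts to a standard deviation score (SDS, z-score) by

    z = ((x / M)**L - 1) / (L * S)      if L != 0
    z = ln(x / M) / S                   if L == 0

with L, M and S interpolated linearly in age between tabulated grid rows.
This module implements both directions of the transform for height-for-age
(age in years) and birthweight-for-gestation (age in completed weeks),
reads user-supplied LMS tables from CSV, and ships smooth synthetic
reference tables so that the rest of the package is testable without
redistributing copyrighted national reference data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Sex",
    "MeasurementKind",
    "LMSReference",
    "Measurement",
    "GrowthReferenceError",
    "ReferenceFormatError",
    "ReferenceValidationError",
    "AgeOutOfRangeError",
    "SexMismatchError",
    "read_lms_table",
    "write_lms_table",
    "lms_zscore",
    "lms_value",
    "centile_to_z",
    "synthetic_female_height_reference",
    "synthetic_birthweight_reference",
]

#: |L| below this is treated as the log (L -> 0) branch of the transform.
L_ZERO_TOLERANCE = 1e-7


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class MeasurementKind(str, enum.Enum):
    HEIGHT_FOR_AGE = "height_for_age"
    BIRTHWEIGHT_FOR_GESTATION = "birthweight_for_gestation"


class GrowthReferenceError(Exception):
    """Base class for growth-reference errors."""


class ReferenceFormatError(GrowthReferenceError):
    """The reference table file is malformed (bad header, duplicate ages)."""


class ReferenceValidationError(GrowthReferenceError):
    """The reference table violates an LMS invariant (M <= 0, too few rows)."""


class AgeOutOfRangeError(GrowthReferenceError):
    """Requested age lies outside the reference grid; no extrapolation."""


class SexMismatchError(GrowthReferenceError):
    """Measurement sex does not match the reference sex."""


@dataclass(frozen=True)
class LMSReference:
    """A sex- and measurement-specific grid of (age, L, M, S).

    Ages are years for height-for-age and completed weeks of gestation for
    birthweight-for-gestation.  M is in the measurement's unit (cm or g);
    L and S are dimensionless.
    """

    sex: Sex
    measurement: MeasurementKind
    ages: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ages", "L", "M", "S"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        n = self.ages.size
        if n < 2:
            raise ReferenceValidationError(
                f"LMS grid needs at least 2 rows, got {n}"
            )
        if not (self.L.size == self.M.size == self.S.size == n):
            raise ReferenceValidationError("L, M, S and age columns differ in length")
        if np.any(np.diff(self.ages) <= 0):
            raise ReferenceValidationError("grid ages must be strictly increasing")
        if np.any(self.M <= 0):
            raise ReferenceValidationError("M must be positive at every grid age")
        if np.any(self.S <= 0):
            raise ReferenceValidationError("S must be positive at every grid age")

    @property
    def age_min(self) -> float:
        return float(self.ages[0])

    @property
    def age_max(self) -> float:
        return float(self.ages[-1])

    def interpolate(self, age: float) -> tuple[float, float, float]:
        """Return (L, M, S) at ``age``, linear in age component-wise."""
        self._check_age(age)
        return (
            float(np.interp(age, self.ages, self.L)),
            float(np.interp(age, self.ages, self.M)),
            float(np.interp(age, self.ages, self.S)),
        )

    def _check_age(self, age: float) -> None:
        if not (self.age_min <= age <= self.age_max):
            raise AgeOutOfRangeError(
                f"age {age} outside reference grid "
                f"[{self.age_min}, {self.age_max}] for {self.measurement.value}"
            )

    def equals(self, other: "LMSReference") -> bool:
        return (
            self.sex == other.sex
            and self.measurement == other.measurement
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.L, other.L)
            and np.array_equal(self.M, other.M)
            and np.array_equal(self.S, other.S)
        )


@dataclass(frozen=True)
class Measurement:
    """One raw measurement: cm at an age in years, or g at a gestation in weeks."""

    value: float
    age: float
    sex: Sex = Sex.FEMALE

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"measurement value must be positive, got {self.value}")


def read_lms_table(path, sex: Sex, measurement: MeasurementKind) -> LMSReference:
    """Read an LMS reference table from CSV.

    Expected format: header ``age,L,M,S``, one row per grid age, dot
    decimals, UTF-8.  Rows may appear in any order; the returned reference
    is sorted ascending by age.  Duplicate ages are a format error.
    """
    df = pd.read_csv(path, encoding="utf-8")
    expected = ["age", "L", "M", "S"]
    if list(df.columns) != expected:
        raise ReferenceFormatError(
            f"expected header {','.join(expected)}, got {','.join(map(str, df.columns))}"
        )
    if df["age"].duplicated().any():
        dupes = sorted(df.loc[df["age"].duplicated(), "age"].unique())
        raise ReferenceFormatError(f"duplicate grid ages: {dupes}")
    df = df.sort_values("age", kind="mergesort").reset_index(drop=True)
    return LMSReference(
        sex=sex,
        measurement=measurement,
        ages=df["age"].to_numpy(float),
        L=df["L"].to_numpy(float),
        M=df["M"].to_numpy(float),
        S=df["S"].to_numpy(float),
    )


def write_lms_table(ref: LMSReference, path) -> None:
    """Write a reference back to the ``age,L,M,S`` CSV format."""
    pd.DataFrame(
        {"age": ref.ages, "L": ref.L, "M": ref.M, "S": ref.S}
    ).to_csv(path, index=False)


def _zscore_at(value: float, L: float, M: float, S: float) -> float:
    if abs(L) < L_ZERO_TOLERANCE:
        return float(np.log(value / M) / S)
    return float(((value / M) ** L - 1.0) / (L * S))


def lms_zscore(m: Measurement, ref: LMSReference) -> float:
    """Convert a measurement to an SDS against ``ref``.

    L, M and S are linearly interpolated at ``m.age``; ages outside the
    grid raise :class:`AgeOutOfRangeError` rather than extrapolating.
    """
    if m.sex != ref.sex:
        raise SexMismatchError(
            f"measurement sex {m.sex.value!r} vs reference sex {ref.sex.value!r}"
        )
    L, M, S = ref.interpolate(m.age)
    return _zscore_at(m.value, L, M, S)


def lms_value(z: float, age: float, sex: Sex, ref: LMSReference) -> float:
    """Inverse transform: the measurement value at SDS ``z`` and ``age``.

    For L < 0 (and extreme positive L) some z drive the inverse
    ``M * (1 + L*S*z)**(1/L)`` non-positive; those raise a ValueError
    reporting the admissible z bound.
    """
    if sex != ref.sex:
        raise SexMismatchError(
            f"requested sex {sex.value!r} vs reference sex {ref.sex.value!r}"
        )
    L, M, S = ref.interpolate(age)
    if abs(L) < L_ZERO_TOLERANCE:
        return float(M * np.exp(S * z))
    base = 1.0 + L * S * z
    if base <= 0:
        bound = -1.0 / (L * S)
        side = ">" if L * S < 0 else "<"
        raise ValueError(
            f"z={z} outside the admissible domain at age {age} "
            f"(requires z {side} {bound:.6g} for L={L:.4g})"
        )
    return float(M * base ** (1.0 / L))


def centile_to_z(centile: float) -> float:
    """Standard-normal quantile of a centile given in percent (0 < c < 100)."""
    if not 0.0 < centile < 100.0:
        raise ValueError(f"centile must be strictly between 0 and 100, got {centile}")
    return float(stats.norm.ppf(centile / 100.0))


# ---------------------------------------------------------------------------
# Synthetic analytic references
# ---------------------------------------------------------------------------

# Hand-anchored female height-for-age medians (cm), roughly tracking the
# shape of a northern-European girls' chart, with L = 1 and constant S so
# every expected value in the test-suite has a closed form.  These tables
# are synthetic stand-ins for real national references, which are
# user-supplied input and never bundled.
_FEMALE_HEIGHT_AGES = np.arange(1.0, 22.0)
_FEMALE_HEIGHT_M = np.array([
    74.5, 86.0, 94.5, 102.0, 109.0, 115.5, 121.5, 127.5, 133.0, 138.5,
    144.5, 151.0, 156.5, 160.0, 162.0, 163.0, 163.5, 163.6, 163.65, 163.7,
    163.7,
])
_FEMALE_HEIGHT_S = 0.037

_BIRTHWEIGHT_WEEKS = np.array([24.0, 26, 28, 30, 32, 34, 36, 38, 40, 42, 44])
_BIRTHWEIGHT_M = np.array(
    [700.0, 950, 1200, 1550, 1950, 2400, 2850, 3200, 3480, 3620, 3650]
)
_BIRTHWEIGHT_S = 0.13


def synthetic_female_height_reference() -> LMSReference:
    """Synthetic analytic female height-for-age reference, ages 1-21 y.

    L = 1 and S = 0.037 everywhere, so at each age the reference
    distribution is Normal(M, M*S); at age 20 the median is 163.7 cm with
    SD 6.06 cm, close to a young-adult female population.
    """
    return LMSReference(
        sex=Sex.FEMALE,
        measurement=MeasurementKind.HEIGHT_FOR_AGE,
        ages=_FEMALE_HEIGHT_AGES,
        L=np.ones_like(_FEMALE_HEIGHT_AGES),
        M=_FEMALE_HEIGHT_M,
        S=np.full_like(_FEMALE_HEIGHT_AGES, _FEMALE_HEIGHT_S),
    )


def synthetic_birthweight_reference() -> LMSReference:
    """Synthetic analytic birthweight-for-gestation reference, 24-44 weeks.

    L = 1 and S = 0.13, giving a term (40-week) median of 3480 g with an
    SD of about 452 g.  Gestations recorded in completed weeks are used
    as-is (week + 0.0).
    """
    return LMSReference(
        sex=Sex.FEMALE,
        measurement=MeasurementKind.BIRTHWEIGHT_FOR_GESTATION,
        ages=_BIRTHWEIGHT_WEEKS,
        L=np.ones_like(_BIRTHWEIGHT_WEEKS),
        M=_BIRTHWEIGHT_M,
        S=np.full_like(_BIRTHWEIGHT_WEEKS, _BIRTHWEIGHT_S),
    )
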