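"""Mid-parental height, parental target range, and their SDS.

For a girl, the mid-parental height (MPH) is
``(mother_cm + father_cm - 12.5) / 2`` — the Tanner-style daughter
convention in which 12.5 cm is the mean adult male-female height
difference.  The lower end of the parental target range (LTR) is taken as
8.5 cm (about two SDs of adult female height) below MPH.  Both are
expressed as SDS on the female height reference at the adult age of 20
years, so that a girl's own height SDS can be compared directly with her
family's expected range.

Parental heights carry provenance (measured at clinic, reported by the
parent, or missing); reported heights are accepted but never silently
treated as measured, because reported heights are known to be biased.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .growth_reference import LMSReference, Measurement, lms_zscore

__all__ = [
    "DAUGHTER_CORRECTION_CM",
    "TARGET_RANGE_HALF_WIDTH_CM",
    "ADULT_REFERENCE_AGE",
    "HeightSource",
    "Completeness",
    "ParentalHeights",
    "TargetRange",
    "MissingParentError",
    "mid_parental_height",
    "lower_target_range",
    "measurement_audit_stratum",
    "target_range_sds",
]

#: Mean adult male-female height gap; subtracted before averaging for a daughter.
DAUGHTER_CORRECTION_CM = 12.5
#: Two SDs of adult female height; MPH minus this is the lower target range.
TARGET_RANGE_HALF_WIDTH_CM = 8.5
#: Adult age (years) at which MPH and LTR are converted to SDS.
ADULT_REFERENCE_AGE = 20.0


class HeightSource(str, enum.Enum):
    MEASURED = "measured"
    REPORTED = "reported"
    MISSING = "missing"


class Completeness(str, enum.Enum):
    """Parental-measurement stratum of a target range."""

    BOTH_MEASURED = "both_measured"
    ONE_MEASURED = "one_measured"
    BOTH_REPORTED = "both_reported"
    INSUFFICIENT = "insufficient"


class MissingParentError(ValueError):
    """Raised when MPH is requested but a parental height is absent."""

    def __init__(self, missing: tuple[str, ...]):
        self.missing = missing
        super().__init__(f"missing parental height(s): {', '.join(missing)}")


@dataclass(frozen=True)
class ParentalHeights:
    """Heights of a girl's parents with measurement provenance."""

    mother_cm: float | None
    father_cm: float | None
    mother_source: HeightSource = HeightSource.MEASURED
    father_source: HeightSource = HeightSource.MEASURED

    def __post_init__(self) -> None:
        for height, source, who in (
            (self.mother_cm, self.mother_source, "mother"),
            (self.father_cm, self.father_source, "father"),
        ):
            if (height is None) != (source == HeightSource.MISSING):
                raise ValueError(
                    f"{who}: source must be 'missing' exactly when the height is absent"
                )
            if height is not None and not (100.0 < height < 250.0):
                raise ValueError(
                    f"{who} height {height} cm outside the plausible (100, 250) range"
                )

    @property
    def both_present(self) -> bool:
        return self.mother_cm is not None and self.father_cm is not None


@dataclass(frozen=True)
class TargetRange:
    """MPH and LTR in cm and SDS, with the parental-measurement stratum.

    When a parental height is missing the numeric fields are ``None`` and
    ``completeness`` is :attr:`Completeness.INSUFFICIENT`; callers must
    branch on it, mirroring the per-stratum analyses.
    """

    mph_cm: float | None
    ltr_cm: float | None
    mph_sds: float | None
    ltr_sds: float | None
    completeness: Completeness

    def __post_init__(self) -> None:
        if self.completeness != Completeness.INSUFFICIENT:
            if self.mph_sds is not None and self.ltr_sds is not None:
                if not self.ltr_sds < self.mph_sds:
                    raise ValueError("LTR SDS must lie strictly below MPH SDS")


def mid_parental_height(
    p: ParentalHeights, correction_cm: float = DAUGHTER_CORRECTION_CM
) -> float:
    """Mid-parental height for a daughter: (mother + father - correction) / 2."""
    missing = tuple(
        who
        for who, h in (("mother", p.mother_cm), ("father", p.father_cm))
        if h is None
    )
    if missing:
        raise MissingParentError(missing)
    return (p.mother_cm + p.father_cm - correction_cm) / 2.0


def lower_target_range(
    mph_cm: float, half_width_cm: float = TARGET_RANGE_HALF_WIDTH_CM
) -> float:
    """Lower end of the parental target range: MPH minus ``half_width_cm``."""
    return mph_cm - half_width_cm


def completeness_of(p: ParentalHeights) -> Completeness:
    """Parental-measurement stratum implied by the two provenance flags."""
    if not p.both_present:
        return Completeness.INSUFFICIENT
    sources = {p.mother_source, p.father_source}
    if sources == {HeightSource.MEASURED}:
        return Completeness.BOTH_MEASURED
    if sources == {HeightSource.REPORTED}:
        return Completeness.BOTH_REPORTED
    return Completeness.ONE_MEASURED


def measurement_audit_stratum(p: ParentalHeights) -> str:
    """Audit stratum by how many parents were actually *measured*.

    Unlike :func:`completeness_of` this ignores whether the unmeasured
    height was reported or absent — it answers the service-audit question
    "were both parents measured in clinic?".
    """
    n = sum(
        s == HeightSource.MEASURED for s in (p.mother_source, p.father_source)
    )
    return ("neither_measured", "one_measured", "both_measured")[n]


def target_range_sds(
    p: ParentalHeights,
    female_ref: LMSReference,
    adult_age: float = ADULT_REFERENCE_AGE,
    correction_cm: float = DAUGHTER_CORRECTION_CM,
    half_width_cm: float = TARGET_RANGE_HALF_WIDTH_CM,
) -> TargetRange:
    """Compute the full target range for a girl's parents.

    MPH and LTR are converted to SDS at ``adult_age`` on the female height
    reference.  A missing parent yields an insufficient-data range rather
    than an exception, so cohort pipelines can stratify on completeness.
    """
    completeness = completeness_of(p)
    if completeness == Completeness.INSUFFICIENT:
        return TargetRange(None, None, None, None, completeness)
    mph = mid_parental_height(p, correction_cm)
    ltr = lower_target_range(mph, half_width_cm)
    mph_sds = lms_zscore(
        Measurement(value=mph, age=adult_age, sex=female_ref.sex), female_ref
    )
    ltr_sds = lms_zscore(
        Measurement(value=ltr, age=adult_age, sex=female_ref.sex), female_ref
    )
    return TargetRange(mph, ltr, mph_sds, ltr_sds, completeness)
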