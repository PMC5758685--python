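"""Classification against population and family thresholds, and
screening-sensitivity summaries.

Each girl's height SDS at her first accurate measurement (after age 1
year, before any growth-promoting treatment) is compared against

* the population short-stature cut-off, Ht SDS < -2, and
* her family's lower target range, Ht SDS < LTR SDS,

both with strict inequality (a girl at exactly -2.00 SDS is not short).
Counts are banded by age at first measurement (1-5, 5.1-10, 10.1-16
years) to show how family-referenced screening performs across childhood,
and birthweight SDS is tallied against configurable cut-offs.  A small
worked-example calculator gives the predictive yield of crude
short-stature screening at population scale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .parental_targets import HeightSource, ParentalHeights, TargetRange
from .growth_reference import LMSReference, Measurement, lms_zscore

__all__ = [
    "Karyotype",
    "AgeBand",
    "GirlRecord",
    "ClassifiedRecord",
    "SensitivityTable",
    "BandCounts",
    "ExcludedRecordError",
    "POPULATION_SHORT_CUTOFF",
    "DEFAULT_BW_CUTOFFS",
    "round_half_even",
    "format_percent",
    "assign_age_band",
    "classify",
    "classify_sds",
    "sensitivity_table",
    "short_stature_sensitivity",
    "birthweight_sensitivity",
    "crude_screening_yield",
    "CrudeScreeningYield",
]

#: Population short-stature threshold (strict: short means Ht SDS < -2).
POPULATION_SHORT_CUTOFF = -2.0

#: Birthweight SDS cut-offs examined for screening sensitivity.
DEFAULT_BW_CUTOFFS = (-2.0, -1.5, -1.0)


class Karyotype(str, enum.Enum):
    """Karyotype categories; mosaics with a normal or triple-X line are milder."""

    MONOSOMY_45X = "45X"
    ISO_XQ_MOSAIC = "45X_46XiXq"
    XY_MOSAIC = "45X_46XY"
    XX_MOSAIC = "45X_46XX"
    TRIPLE_X_MOSAIC = "45X_47XXX"
    RING_X_MOSAIC = "45X_46XrX"
    ISO_XQ = "46XiXq"
    OTHER = "other"


#: Karyotypes associated with a milder height phenotype.
MILD_KARYOTYPES = frozenset({Karyotype.XX_MOSAIC, Karyotype.TRIPLE_X_MOSAIC})


class AgeBand(str, enum.Enum):
    BAND_1_5 = "band_1_5"
    BAND_5_10 = "band_5_10"
    BAND_10_16 = "band_10_16"
    OUT_OF_BAND = "out_of_band"


_BANDS_IN_ORDER = (AgeBand.BAND_1_5, AgeBand.BAND_5_10, AgeBand.BAND_10_16)

BAND_LABELS = {
    AgeBand.BAND_1_5: "1-5 years",
    AgeBand.BAND_5_10: "5.1-10 years",
    AgeBand.BAND_10_16: "10.1-16 years",
    AgeBand.OUT_OF_BAND: "> 16 years",
}


class ExcludedRecordError(Exception):
    """A record cannot enter the analysis; carries the exclusion reason."""

    def __init__(self, record_id: str, reason: str):
        self.record_id = record_id
        self.reason = reason
        super().__init__(f"{record_id}: {reason}")


@dataclass(frozen=True)
class GirlRecord:
    """One study subject at her first accurate height measurement.

    Either ``height_cm`` (converted via a reference) or ``height_sds``
    (pre-computed) must be present; when both are, the SDS wins so that
    fixtures carrying published SDS values are never re-derived against a
    different reference.
    """

    id: str
    age_first_measurement: float
    height_cm: float | None = None
    height_sds: float | None = None
    birthweight_g: float | None = None
    gestation_weeks: float | None = None
    karyotype: Karyotype = Karyotype.MONOSOMY_45X
    parents: ParentalHeights = field(
        default_factory=lambda: ParentalHeights(
            None, None, HeightSource.MISSING, HeightSource.MISSING
        )
    )

    def __post_init__(self) -> None:
        if self.height_cm is None and self.height_sds is None:
            raise ValueError(f"{self.id}: neither height_cm nor height_sds present")


@dataclass(frozen=True)
class ClassifiedRecord:
    """Derived screening quantities for one girl."""

    id: str
    age_years: float
    age_band: AgeBand
    ht_sds: float
    ltr_sds: float | None
    bw_sds: float | None
    short_population: bool
    below_family: bool | None
    bw_below: dict[float, bool]


def round_half_even(x: float, decimals: int = 0) -> float:
    """Round-half-to-even, the package's single percentage rounding rule."""
    return round(x, decimals) if decimals else float(round(x))


def format_percent(
    numerator: int, denominator: int, decimals: int = 0, truncate: bool = False
) -> float:
    """Percentage with round-half-even display rounding.

    ``truncate=True`` chops instead of rounding — a compatibility mode for
    comparison against older reports whose percentages were truncated.
    """
    if denominator == 0:
        raise ZeroDivisionError("empty denominator for a percentage")
    pct = 100.0 * numerator / denominator
    if truncate:
        factor = 10.0 ** decimals
        out = math.floor(pct * factor) / factor
    else:
        out = round_half_even(pct, decimals)
    return int(out) if decimals == 0 else out


def assign_age_band(age_years: float) -> AgeBand:
    """Band by age at first measurement: (1, 5], (5, 10], (10, 16], else out."""
    if 1.0 < age_years <= 5.0:
        return AgeBand.BAND_1_5
    if age_years <= 10.0:
        return AgeBand.BAND_5_10
    if age_years <= 16.0:
        return AgeBand.BAND_10_16
    return AgeBand.OUT_OF_BAND


def classify_sds(
    record_id: str,
    age_years: float,
    ht_sds: float,
    ltr_sds: float | None = None,
    bw_sds: float | None = None,
    bw_cutoffs: tuple[float, ...] = DEFAULT_BW_CUTOFFS,
) -> ClassifiedRecord:
    """Classify from already-derived SDS values (strict < comparisons)."""
    if age_years <= 1.0:
        raise ExcludedRecordError(record_id, "age at first measurement <= 1 year")
    return ClassifiedRecord(
        id=record_id,
        age_years=age_years,
        age_band=assign_age_band(age_years),
        ht_sds=ht_sds,
        ltr_sds=ltr_sds,
        bw_sds=bw_sds,
        short_population=ht_sds < POPULATION_SHORT_CUTOFF,
        below_family=None if ltr_sds is None else ht_sds < ltr_sds,
        bw_below={} if bw_sds is None else {c: bw_sds < c for c in bw_cutoffs},
    )


def classify(
    g: GirlRecord,
    height_ref: LMSReference | None = None,
    bw_ref: LMSReference | None = None,
    target: TargetRange | None = None,
    bw_cutoffs: tuple[float, ...] = DEFAULT_BW_CUTOFFS,
) -> ClassifiedRecord:
    """Classify one girl against population and family thresholds.

    Height SDS is taken from the record when present, otherwise derived
    from ``height_cm`` via ``height_ref``.  Birthweight SDS is derived only
    when both birthweight and gestation are recorded and ``bw_ref`` is
    given.  Ages <= 1 year raise :class:`ExcludedRecordError` so pipelines
    can log and count the exclusion instead of silently dropping it.
    """
    if g.height_sds is not None:
        ht_sds = g.height_sds
    else:
        if height_ref is None:
            raise ValueError(f"{g.id}: height_cm given but no height reference")
        ht_sds = lms_zscore(
            Measurement(g.height_cm, g.age_first_measurement, height_ref.sex),
            height_ref,
        )
    bw_sds = None
    if (
        bw_ref is not None
        and g.birthweight_g is not None
        and g.gestation_weeks is not None
    ):
        bw_sds = lms_zscore(
            Measurement(g.birthweight_g, float(g.gestation_weeks), bw_ref.sex),
            bw_ref,
        )
    ltr_sds = None
    if target is not None and target.ltr_sds is not None:
        ltr_sds = target.ltr_sds
    return classify_sds(
        g.id, g.age_first_measurement, ht_sds, ltr_sds, bw_sds, bw_cutoffs
    )


@dataclass(frozen=True)
class BandCounts:
    """Counts for one age band of the family-referenced contingency table."""

    n_total: int
    n_below_ltr: int
    n_short_population: int

    @property
    def n_at_or_above_ltr(self) -> int:
        return self.n_total - self.n_below_ltr

    @property
    def n_not_short(self) -> int:
        return self.n_total - self.n_short_population


@dataclass(frozen=True)
class SensitivityTable:
    """Age-banded counts below/at-or-above the family and population cut-offs.

    ``bands`` maps each in-range band to its counts; ``overall`` covers the
    1-16 year range (bands summed).  Percentages use round-half-even
    integer display, matching how such contingency tables are reported.
    """

    bands: dict[AgeBand, BandCounts]
    overall: BandCounts

    def percent_below_ltr(self, band: AgeBand | None = None, decimals: int = 0) -> float:
        c = self.overall if band is None else self.bands[band]
        return format_percent(c.n_below_ltr, c.n_total, decimals)

    def percent_short_population(
        self, band: AgeBand | None = None, decimals: int = 0
    ) -> float:
        c = self.overall if band is None else self.bands[band]
        return format_percent(c.n_short_population, c.n_total, decimals)

    def sensitivity_below_ltr(self) -> float:
        """Overall family-referenced sensitivity as a proportion."""
        return self.overall.n_below_ltr / self.overall.n_total


def sensitivity_table(records: list[ClassifiedRecord]) -> SensitivityTable:
    """Build the age-banded family-vs-population contingency table.

    Every record must carry an LTR SDS (this table describes the
    both-parents-measured stratum); records older than 16 years fall
    outside the banded range and are not included.
    """
    if not records:
        raise ValueError("sensitivity_table requires at least one record")
    missing = [r.id for r in records if r.below_family is None]
    if missing:
        raise ValueError(
            f"records without LTR SDS cannot enter the family table: {missing[:5]}"
        )
    bands: dict[AgeBand, BandCounts] = {}
    for band in _BANDS_IN_ORDER:
        rs = [r for r in records if r.age_band == band]
        bands[band] = BandCounts(
            n_total=len(rs),
            n_below_ltr=sum(r.below_family for r in rs),
            n_short_population=sum(r.short_population for r in rs),
        )
    overall = BandCounts(
        n_total=sum(b.n_total for b in bands.values()),
        n_below_ltr=sum(b.n_below_ltr for b in bands.values()),
        n_short_population=sum(b.n_short_population for b in bands.values()),
    )
    return SensitivityTable(bands=bands, overall=overall)


def short_stature_sensitivity(
    records: list[ClassifiedRecord], decimals: int = 1
) -> tuple[int, int, float]:
    """Crude short-stature screening over a whole cohort.

    Returns (n short, n total, percent short) where short means
    Ht SDS < -2 strictly.  Unlike the family table this needs no LTR.
    """
    if not records:
        raise ValueError("no records")
    n_short = sum(r.short_population for r in records)
    return n_short, len(records), format_percent(n_short, len(records), decimals)


def birthweight_sensitivity(
    records: list[ClassifiedRecord],
    cutoffs: tuple[float, ...] = DEFAULT_BW_CUTOFFS,
    decimals: int = 1,
) -> dict[float, tuple[int, float]]:
    """Count of bw_sds < c and its percentage, per cut-off c.

    The denominator is the number of records with a birthweight SDS; the
    caller is responsible for outlier exclusion before this tally.
    """
    with_bw = [r for r in records if r.bw_sds is not None]
    if not with_bw:
        raise ValueError("no records with birthweight SDS")
    out: dict[float, tuple[int, float]] = {}
    for c in cutoffs:
        n = sum(r.bw_sds < c for r in with_bw)
        out[c] = (n, format_percent(n, len(with_bw), decimals))
    return out


@dataclass(frozen=True)
class CrudeScreeningYield:
    """Outcome of the population-scale short-stature screening example."""

    n_short_girls: float
    n_ts_girls: float
    ppv_percent: float


def crude_screening_yield(
    annual_births: float,
    female_fraction: float,
    ts_prevalence: float,
    short_centile: float,
    paper_compat: bool = True,
) -> CrudeScreeningYield:
    """Predictive yield of flagging every girl below a height centile.

    Of ``annual_births`` live births, ``female_fraction`` are girls; by
    definition ``short_centile`` percent of girls fall below that centile,
    and ``ts_prevalence`` (per female birth) have Turner syndrome.  The
    positive predictive value is the Turner girls as a fraction of all
    short girls, reported in percent.

    In ``paper_compat`` mode intermediate counts are rounded the way such
    back-of-envelope figures are quoted — short girls to the nearest
    hundred, affected girls to the nearest integer — and the PPV to one
    decimal.  Otherwise all quantities are exact expectations.

    Note: this figure is a PPV (true positives among screen positives),
    even though it is sometimes loosely labelled a specificity.
    """
    if annual_births <= 0 or not 0 < female_fraction <= 1:
        raise ValueError("annual_births must be positive and female_fraction in (0, 1]")
    if not 0 < short_centile < 100:
        raise ValueError("short_centile must be strictly between 0 and 100")
    if ts_prevalence < 0:
        raise ValueError("ts_prevalence cannot be negative")
    girls = annual_births * female_fraction
    n_short = girls * short_centile / 100.0
    n_ts = girls * ts_prevalence
    if paper_compat:
        n_short = round_half_even(n_short / 100.0) * 100.0
        n_ts = round_half_even(n_ts)
        ppv = format_percent(int(n_ts), int(n_short), decimals=1)
    else:
        ppv = 100.0 * n_ts / n_short if n_short > 0 else 0.0
    return CrudeScreeningYield(n_short, n_ts, ppv if n_ts > 0 else 0.0)
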