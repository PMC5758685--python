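"""Synthetic Turner-syndrome cohort generator.

Real case-note data of the kind this analysis runs on are not publicly
deposited, so the package ships a generator that emulates the cohort
structure the screening analysis assumes:

* an age at first accurate measurement drawn from a truncated normal,
* parental heights drawn independently per parent,
* a girl's height SDS built as
  ``coupling * MPH_SDS + deficit(age) + karyotype_offset + residual``,
  where ``deficit`` is a plateau-then-decline piecewise-linear function of
  age (growth in Turner syndrome is near-normal over the first 3-4 years,
  with height falling progressively away from the population centiles
  thereafter), and mosaic karyotypes with a normal or triple-X cell line
  receive a milder (less negative) offset,
* a below-average birthweight SDS converted to grams through the
  birthweight-for-gestation reference, and
* parental measurement provenance (both measured / one measured / neither)
  with configurable biases applied to reported heights (fathers
  over-report, mothers under-report).

Everything is driven by one seeded generator per call; the same
configuration and seed reproduce a byte-identical cohort.  The default
configuration is calibrated so the analytic expectations of the model
match the cohort statistics the analysis is designed around
(mean Ht SDS -2.63, SD 0.94; mean LTR SDS -1.77, SD 0.81).
"""

from __future__ import annotations

import io
import csv
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import integrate, stats

from .growth_reference import LMSReference, Sex, lms_value
from .parental_targets import (
    ADULT_REFERENCE_AGE,
    DAUGHTER_CORRECTION_CM,
    TARGET_RANGE_HALF_WIDTH_CM,
    HeightSource,
    ParentalHeights,
)
from .screening import GirlRecord, Karyotype

__all__ = [
    "AgeDistribution",
    "TurnerDeficit",
    "SimulationConfig",
    "default_turner_config",
    "turner_deficit",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "expected_statistics",
    "CohortExpectation",
    "COHORT_CSV_HEADER",
]

COHORT_CSV_HEADER = [
    "id", "age_years", "height_cm", "height_sds", "birthweight_g",
    "gestation_weeks", "karyotype", "mother_cm", "mother_source",
    "father_cm", "father_source",
]


@dataclass(frozen=True)
class AgeDistribution:
    """Truncated-normal age at first accurate measurement, in years."""

    mean: float = 7.05
    sd: float = 4.05
    min: float = 1.31
    max: float = 18.5


@dataclass(frozen=True)
class TurnerDeficit:
    """Piecewise-linear height deficit (SDS) as a function of age.

    Constant at ``deficit_at_1y`` up to ``plateau_age``, then declining
    linearly at ``slope_after_plateau`` (SDS per year, negative).
    """

    deficit_at_1y: float = -2.11
    slope_after_plateau: float = -0.12
    plateau_age: float = 4.0


# Karyotype mix of the both-parents-measured stratum the defaults emulate
# (category counts out of 94).
_DEFAULT_KARYOTYPE_MIX = {
    Karyotype.MONOSOMY_45X: 34 / 94,
    Karyotype.ISO_XQ_MOSAIC: 17 / 94,
    Karyotype.XY_MOSAIC: 6 / 94,
    Karyotype.XX_MOSAIC: 5 / 94,
    Karyotype.TRIPLE_X_MOSAIC: 7 / 94,
    Karyotype.RING_X_MOSAIC: 7 / 94,
    Karyotype.ISO_XQ: 5 / 94,
    Karyotype.OTHER: 13 / 94,
}

# Discrete gestation distribution (completed weeks), centred on 39-40 and
# spanning 27-44 weeks.
_DEFAULT_GESTATION_PMF = {
    27: 0.01, 28: 0.01, 29: 0.01, 30: 0.015, 31: 0.015, 32: 0.02,
    33: 0.02, 34: 0.03, 35: 0.04, 36: 0.06, 37: 0.09, 38: 0.15,
    39: 0.21, 40: 0.20, 41: 0.09, 42: 0.02, 43: 0.005, 44: 0.005,
}

_MILD_KARYOTYPES = (Karyotype.XX_MOSAIC, Karyotype.TRIPLE_X_MOSAIC)


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of the synthetic Turner-cohort generator."""

    n_girls: int = 92
    seed: int = 0
    age_distribution: AgeDistribution = field(default_factory=AgeDistribution)
    maternal_height: tuple[float, float] = (160.0, 6.9)   # (mean cm, sd cm)
    paternal_height: tuple[float, float] = (175.5, 7.0)
    #: Regression coefficient of the girl's Ht SDS on mid-parental SDS.
    parent_child_coupling: float = 0.4
    turner_deficit: TurnerDeficit = field(default_factory=TurnerDeficit)
    karyotype_mix: dict[Karyotype, float] = field(
        default_factory=lambda: dict(_DEFAULT_KARYOTYPE_MIX)
    )
    #: SDS added for the milder mosaic karyotypes (45,X/46,XX; 45,X/47,XXX).
    mild_karyotype_offset: float = 0.7
    residual_sd: float = 0.76
    bw_sds_distribution: tuple[float, float] = (-0.91, 1.1)
    #: P(both parents measured), P(exactly one), P(neither).
    parental_measurement_missingness: tuple[float, float, float] = (
        94 / 172, 37 / 172, 41 / 172,
    )
    #: (father over-reports by, mother under-reports by), in cm.
    reported_height_bias: tuple[float, float] = (2.5, 2.5)
    #: When one parent is unmeasured, probability the measured one is the mother.
    p_mother_measured_when_one: float = 0.97
    #: Probability an unmeasured height is reported rather than absent.
    p_reported_when_unmeasured: float = 0.37
    #: Probability birthweight and gestation were recorded.
    p_birth_data: float = 0.79
    gestation_pmf: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_GESTATION_PMF)
    )

    def validate(self) -> None:
        if self.n_girls < 1:
            raise ValueError("n_girls must be >= 1")
        if self.residual_sd < 0 or self.age_distribution.sd <= 0:
            raise ValueError("standard deviations must be positive")
        if self.turner_deficit.plateau_age < 1.0:
            raise ValueError("plateau_age must be >= 1 year")
        for name, pmf in (
            ("karyotype_mix", self.karyotype_mix),
            ("gestation_pmf", self.gestation_pmf),
        ):
            total = sum(pmf.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in pmf.values()):
                raise ValueError(f"{name} has a negative probability")
        total = sum(self.parental_measurement_missingness)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"parental_measurement_missingness sums to {total}, not 1"
            )
        if not 0 <= self.p_birth_data <= 1:
            raise ValueError("p_birth_data must be a probability")

    # -- structured-text (YAML) round trip ---------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["karyotype_mix"] = {k.value: v for k, v in self.karyotype_mix.items()}
        d["age_distribution"] = asdict(self.age_distribution)
        d["turner_deficit"] = asdict(self.turner_deficit)
        d["maternal_height"] = list(self.maternal_height)
        d["paternal_height"] = list(self.paternal_height)
        d["bw_sds_distribution"] = list(self.bw_sds_distribution)
        d["parental_measurement_missingness"] = list(
            self.parental_measurement_missingness
        )
        d["reported_height_bias"] = list(self.reported_height_bias)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["age_distribution"] = AgeDistribution(**d["age_distribution"])
        d["turner_deficit"] = TurnerDeficit(**d["turner_deficit"])
        d["karyotype_mix"] = {
            Karyotype(k): v for k, v in d["karyotype_mix"].items()
        }
        d["gestation_pmf"] = {int(k): v for k, v in d["gestation_pmf"].items()}
        for key in (
            "maternal_height", "paternal_height", "bw_sds_distribution",
            "parental_measurement_missingness", "reported_height_bias",
        ):
            d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text))


def default_turner_config(n_girls: int = 92, seed: int = 0) -> SimulationConfig:
    """The shipped Turner calibration with a chosen cohort size and seed."""
    return SimulationConfig(n_girls=n_girls, seed=seed)


def turner_deficit(age, params: TurnerDeficit):
    """Height deficit in SDS at ``age`` years (vectorised, non-increasing)."""
    age = np.asarray(age, dtype=float)
    out = params.deficit_at_1y + params.slope_after_plateau * np.maximum(
        age - params.plateau_age, 0.0
    )
    return float(out) if out.ndim == 0 else out


def _mph_sds_cm_to_sds(mph_cm, ref: LMSReference, adult_age: float):
    """Convert MPH in cm to SDS at the adult age (vectorised helper)."""
    L, M, S = ref.interpolate(adult_age)
    x = np.asarray(mph_cm, dtype=float) / M
    if abs(L) < 1e-7:
        return np.log(x) / S
    return (x ** L - 1.0) / (L * S)


def simulate_cohort(
    cfg: SimulationConfig,
    height_ref: LMSReference,
    bw_ref: LMSReference | None = None,
) -> list[GirlRecord]:
    """Draw a synthetic cohort of girls, reproducibly for (cfg, cfg.seed).

    The girl's height in cm is obtained by pushing her latent height SDS
    through the inverse LMS transform at her age, so re-deriving SDS in the
    analysis pipeline recovers the latent value exactly.  Parental heights
    are always generated (they drive the coupling term) but are recorded as
    measured, reported-with-bias, or missing according to the missingness
    probabilities.
    """
    cfg.validate()
    ad = cfg.age_distribution
    if not (height_ref.age_min <= ad.min and ad.max <= height_ref.age_max):
        raise ValueError("height reference does not cover the simulated age range")
    height_ref._check_age(ADULT_REFERENCE_AGE)

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_girls

    a, b = (ad.min - ad.mean) / ad.sd, (ad.max - ad.mean) / ad.sd
    ages = stats.truncnorm.rvs(a, b, loc=ad.mean, scale=ad.sd, size=n, random_state=rng)
    mother = np.clip(rng.normal(*cfg.maternal_height, size=n), 110.0, 240.0)
    father = np.clip(rng.normal(*cfg.paternal_height, size=n), 110.0, 240.0)

    karyos = list(cfg.karyotype_mix)
    k_idx = rng.choice(len(karyos), size=n, p=list(cfg.karyotype_mix.values()))
    offsets = np.array(
        [cfg.mild_karyotype_offset if karyos[i] in _MILD_KARYOTYPES else 0.0
         for i in k_idx]
    )
    residuals = rng.normal(0.0, cfg.residual_sd, size=n) if cfg.residual_sd > 0 \
        else np.zeros(n)

    mph_cm = (mother + father - DAUGHTER_CORRECTION_CM) / 2.0
    mph_sds = _mph_sds_cm_to_sds(mph_cm, height_ref, ADULT_REFERENCE_AGE)
    z_girl = (
        cfg.parent_child_coupling * mph_sds
        + turner_deficit(ages, cfg.turner_deficit)
        + offsets
        + residuals
    )

    categories = rng.choice(3, size=n, p=list(cfg.parental_measurement_missingness))
    mother_is_measured_one = rng.random(n) < cfg.p_mother_measured_when_one
    unmeasured_reported = rng.random(n) < cfg.p_reported_when_unmeasured

    bw_present = rng.random(n) < cfg.p_birth_data
    gest_weeks = list(cfg.gestation_pmf)
    gest = rng.choice(gest_weeks, size=n, p=list(cfg.gestation_pmf.values()))
    bw_mean, bw_sd = cfg.bw_sds_distribution
    bw_sds = np.clip(rng.normal(bw_mean, bw_sd, size=n), -6.0, 6.0)

    father_over, mother_under = cfg.reported_height_bias
    records: list[GirlRecord] = []
    for i in range(n):
        height_cm = lms_value(float(z_girl[i]), float(ages[i]), height_ref.sex,
                              height_ref)
        mom_cm, mom_src = float(mother[i]), HeightSource.MEASURED
        dad_cm, dad_src = float(father[i]), HeightSource.MEASURED
        if categories[i] == 1:  # exactly one parent measured
            if mother_is_measured_one[i]:
                if unmeasured_reported[i]:
                    dad_cm, dad_src = dad_cm + father_over, HeightSource.REPORTED
                else:
                    dad_cm, dad_src = None, HeightSource.MISSING
            else:
                if unmeasured_reported[i]:
                    mom_cm, mom_src = mom_cm - mother_under, HeightSource.REPORTED
                else:
                    mom_cm, mom_src = None, HeightSource.MISSING
        elif categories[i] == 2:  # neither measured: both reported, or absent
            if unmeasured_reported[i]:
                mom_cm, mom_src = mom_cm - mother_under, HeightSource.REPORTED
                dad_cm, dad_src = dad_cm + father_over, HeightSource.REPORTED
            else:
                mom_cm, mom_src = None, HeightSource.MISSING
                dad_cm, dad_src = None, HeightSource.MISSING

        birthweight_g = gestation = None
        if bw_present[i] and bw_ref is not None:
            gestation = float(gest[i])
            birthweight_g = lms_value(float(bw_sds[i]), gestation, bw_ref.sex, bw_ref)

        records.append(
            GirlRecord(
                id=f"TS{i + 1:05d}",
                age_first_measurement=float(ages[i]),
                height_cm=height_cm,
                height_sds=None,
                birthweight_g=birthweight_g,
                gestation_weeks=gestation,
                karyotype=karyos[k_idx[i]],
                parents=ParentalHeights(mom_cm, dad_cm, mom_src, dad_src),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Cohort CSV round trip
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float) and x.is_integer():
        return str(int(x))
    return repr(x)


def write_cohort(cohort: list[GirlRecord], path) -> None:
    """Write a cohort to CSV (UTF-8, dot decimal, empty string = missing).

    Floats are written with full round-tripping precision so that
    ``read_cohort`` recovers an equal cohort bit for bit.
    """
    def rows():
        for g in cohort:
            yield [
                g.id, _fmt(g.age_first_measurement), _fmt(g.height_cm),
                _fmt(g.height_sds), _fmt(g.birthweight_g),
                _fmt(g.gestation_weeks), g.karyotype.value,
                _fmt(g.parents.mother_cm), g.parents.mother_source.value,
                _fmt(g.parents.father_cm), g.parents.father_source.value,
            ]

    if hasattr(path, "write"):
        w = csv.writer(path, lineterminator="\n")
        w.writerow(COHORT_CSV_HEADER)
        w.writerows(rows())
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(COHORT_CSV_HEADER)
            w.writerows(rows())


def cohort_to_csv_text(cohort: list[GirlRecord]) -> str:
    buf = io.StringIO()
    write_cohort(cohort, buf)
    return buf.getvalue()


def _parse(s: str) -> float | None:
    return None if s == "" else float(s)


def read_cohort(path) -> list[GirlRecord]:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-made)."""
    close = False
    if hasattr(path, "read"):
        fh = path
    else:
        fh = open(path, newline="", encoding="utf-8")
        close = True
    try:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != COHORT_CSV_HEADER:
            raise ValueError(
                f"bad cohort header: expected {','.join(COHORT_CSV_HEADER)}"
            )
        records = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(COHORT_CSV_HEADER):
                raise ValueError(f"line {lineno}: expected "
                                 f"{len(COHORT_CSV_HEADER)} fields, got {len(row)}")
            try:
                records.append(GirlRecord(
                    id=row[0],
                    age_first_measurement=float(row[1]),
                    height_cm=_parse(row[2]),
                    height_sds=_parse(row[3]),
                    birthweight_g=_parse(row[4]),
                    gestation_weeks=_parse(row[5]),
                    karyotype=Karyotype(row[6]),
                    parents=ParentalHeights(
                        _parse(row[7]), _parse(row[9]),
                        HeightSource(row[8]), HeightSource(row[10]),
                    ),
                ))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
        return records
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Analytic expectations (the Gaussian oracle for parameter recovery)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortExpectation:
    """Analytic moments of the generator's Gaussian model."""

    mean_ht_sds: float
    sd_ht_sds: float
    mean_ltr_sds: float
    sd_ltr_sds: float
    p_below_ltr: float


def expected_statistics(
    cfg: SimulationConfig, height_ref: LMSReference
) -> CohortExpectation:
    """Closed-form expectations of the simulated cohort's key statistics.

    Requires L = 1 at the adult reference age (as in the shipped synthetic
    reference), so the cm -> SDS map is affine and parental-height
    normality carries through exactly.  The below-LTR probability is the
    mixture over age and karyotype of a normal orthant probability:
    conditioned on age and karyotype, ``Ht SDS - LTR SDS`` is Gaussian, so
    P(below) is Phi of the standardised mean gap, integrated over the
    truncated-normal age distribution and summed over the karyotype mix.
    """
    cfg.validate()
    L, M, S = height_ref.interpolate(ADULT_REFERENCE_AGE)
    if abs(L - 1.0) > 1e-9:
        raise ValueError("analytic expectations require L = 1 at the adult age")
    denom = M * S
    mom_mu, mom_sd = cfg.maternal_height
    dad_mu, dad_sd = cfg.paternal_height
    mph_mu_cm = (mom_mu + dad_mu - DAUGHTER_CORRECTION_CM) / 2.0
    mu_m = (mph_mu_cm - M) / denom
    sd_m = 0.5 * float(np.hypot(mom_sd, dad_sd)) / denom
    delta = TARGET_RANGE_HALF_WIDTH_CM / denom

    ad = cfg.age_distribution
    a, b = (ad.min - ad.mean) / ad.sd, (ad.max - ad.mean) / ad.sd
    age_dist = stats.truncnorm(a, b, loc=ad.mean, scale=ad.sd)
    td = cfg.turner_deficit

    def d_of(age):
        return turner_deficit(age, td)

    e_d = age_dist.expect(d_of)
    e_d2 = age_dist.expect(lambda x: d_of(x) ** 2)
    var_d = e_d2 - e_d ** 2

    p_mild = sum(
        p for k, p in cfg.karyotype_mix.items() if k in _MILD_KARYOTYPES
    )
    e_k = cfg.mild_karyotype_offset * p_mild
    var_k = cfg.mild_karyotype_offset ** 2 * p_mild * (1 - p_mild)

    c = cfg.parent_child_coupling
    mean_ht = c * mu_m + e_d + e_k
    var_ht = c ** 2 * sd_m ** 2 + var_d + var_k + cfg.residual_sd ** 2

    # Ht SDS - LTR SDS | age, karyotype  ~  N((c-1)*mu_m + d + k + delta, s2)
    s_gap = float(np.hypot((c - 1.0) * sd_m, cfg.residual_sd))

    def p_below_given_k(k_offset: float) -> float:
        return age_dist.expect(
            lambda age: stats.norm.cdf(
                -((c - 1.0) * mu_m + d_of(age) + k_offset + delta) / s_gap
            )
        )

    p_below = (1 - p_mild) * p_below_given_k(0.0) + p_mild * p_below_given_k(
        cfg.mild_karyotype_offset
    )

    return CohortExpectation(
        mean_ht_sds=float(mean_ht),
        sd_ht_sds=float(np.sqrt(var_ht)),
        mean_ltr_sds=float(mu_m - delta),
        sd_ltr_sds=float(sd_m),
        p_below_ltr=float(p_below),
    )
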