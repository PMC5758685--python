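"""End-to-end analysis pipeline: cohort -> SDS -> target ranges ->
classification -> screening summaries, with explicit exclusion logging.

The pipeline mirrors how a clinic audit of this kind proceeds:

1. every girl's height SDS at first accurate measurement (> 1 year) is
   derived (or taken pre-computed from a fixture),
2. parental target ranges are computed where parental heights exist, and
   each girl is assigned to a parental-measurement stratum
   (both measured / one measured / both reported / insufficient),
3. girls are classified against the population (-2 SDS) and family (LTR)
   thresholds, with strict inequalities,
4. the both-parents-measured stratum yields the age-banded contingency
   table; birthweight cut-off sensitivities are tallied after excluding
   implausible birthweight outliers; per-stratum mean(LTR SDS - Ht SDS)
   differences quantify reported-height bias,
5. a run manifest records every excluded record with its reason so that
   input counts always reconcile.

Also packaged here: a 14-girl fixture of published karyotype / height /
target-range values for girls whose first measurement fell at or above
their family's lower target range — the false-negative profile of
family-referenced screening.
"""

from __future__ import annotations

import hashlib
import io
import csv
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .growth_reference import LMSReference
from .parental_targets import Completeness, TargetRange, target_range_sds
from .screening import (
    DEFAULT_BW_CUTOFFS,
    AgeBand,
    BAND_LABELS,
    ClassifiedRecord,
    ExcludedRecordError,
    GirlRecord,
    Karyotype,
    SensitivityTable,
    birthweight_sensitivity,
    classify,
    classify_sds,
    format_percent,
    sensitivity_table,
    short_stature_sensitivity,
)
from .synthetic_cohort import read_cohort

__all__ = [
    "AnalysisConfig",
    "RunManifest",
    "StratumSummary",
    "AnalysisResult",
    "Table3Girl",
    "FixtureIntegrityError",
    "load_table3_fixture",
    "run_analysis",
    "write_long_results",
    "write_family_table_csv",
    "write_manifest",
]

_TABLE3_RESOURCE = "data/table3_above_ltr_girls.csv"
_TABLE3_SHA256 = "298790585b03378405384f592e7c7cd0be7654c6875d41cd2a03ab9ce26a5d68"

EXCLUSION_REASONS = (
    "age_at_or_below_1_year",
    "no_height_available",
    "manual_exclusion",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Explicit, auditable analysis settings.

    Exclusion rules that a clinic would apply ad hoc (too-early
    measurements, clinically implausible records) are configuration here,
    so every run states them up front.
    """

    min_age_years: float = 1.0
    #: Record ids excluded by hand (clinically implausible measurements).
    manual_exclusions: tuple[str, ...] = ()
    #: |BW SDS| above this is dropped from the birthweight denominator.
    bw_outlier_sds: float = 3.0
    bw_cutoffs: tuple[float, ...] = DEFAULT_BW_CUTOFFS

    def digest(self) -> str:
        text = yaml.safe_dump(
            {
                "min_age_years": self.min_age_years,
                "manual_exclusions": list(self.manual_exclusions),
                "bw_outlier_sds": self.bw_outlier_sds,
                "bw_cutoffs": list(self.bw_cutoffs),
            },
            sort_keys=True,
        )
        return hashlib.sha256(text.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance of one analysis run."""

    cohort_path: str | None
    config_digest: str
    seed: int | None = None
    #: (record id, reason) for records dropped from the height analysis.
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    #: (record id, reason) for records dropped from the birthweight tally only.
    bw_exclusions: list[tuple[str, str]] = field(default_factory=list)
    n_input: int = 0
    n_analysed: int = 0
    timestamp: str | None = None
    outputs: list[str] = field(default_factory=list)

    def reconciles(self) -> bool:
        return self.n_input == self.n_analysed + len(self.exclusions)


@dataclass(frozen=True)
class StratumSummary:
    """Mean height and target-range SDS within one parental stratum."""

    n: int
    mean_ht_sds: float
    mean_ltr_sds: float | None
    #: mean(LTR SDS - Ht SDS); the reported-height bias diagnostic.
    mean_ltr_minus_ht: float | None


@dataclass
class AnalysisResult:
    classified: list[ClassifiedRecord]
    by_stratum: dict[Completeness, list[ClassifiedRecord]]
    family_table: SensitivityTable | None
    crude_short: tuple[int, int, float]
    birthweight: dict[float, tuple[int, float]] | None
    stratum_summaries: dict[Completeness, StratumSummary]
    manifest: RunManifest

    def stratum_percent(self, c: Completeness, decimals: int = 1) -> float:
        return format_percent(
            len(self.by_stratum.get(c, [])), self.manifest.n_analysed, decimals
        )


def run_analysis(
    cohort,
    height_ref: LMSReference,
    bw_ref: LMSReference | None = None,
    config: AnalysisConfig = AnalysisConfig(),
    seed: int | None = None,
) -> AnalysisResult:
    """Run the full screening analysis over a cohort.

    ``cohort`` may be a path to a cohort CSV or a list of
    :class:`GirlRecord`.  Every input record ends up analysed or excluded
    with a logged reason; the manifest reconciles the counts.
    """
    if isinstance(cohort, (str, bytes)) or hasattr(cohort, "__fspath__"):
        records = read_cohort(cohort)
        cohort_path = str(cohort)
    else:
        records, cohort_path = list(cohort), None

    manifest = RunManifest(
        cohort_path=cohort_path,
        config_digest=config.digest(),
        seed=seed,
        n_input=len(records),
    )

    classified: list[ClassifiedRecord] = []
    by_stratum: dict[Completeness, list[ClassifiedRecord]] = {
        c: [] for c in Completeness
    }
    for g in records:
        if g.id in config.manual_exclusions:
            manifest.exclusions.append((g.id, "manual_exclusion"))
            continue
        if g.age_first_measurement <= config.min_age_years:
            manifest.exclusions.append((g.id, "age_at_or_below_1_year"))
            continue
        if g.height_cm is None and g.height_sds is None:
            manifest.exclusions.append((g.id, "no_height_available"))
            continue
        tr: TargetRange = target_range_sds(g.parents, height_ref)
        try:
            rec = classify(
                g, height_ref, bw_ref, target=tr, bw_cutoffs=config.bw_cutoffs
            )
        except ExcludedRecordError as exc:
            manifest.exclusions.append((exc.record_id, exc.reason))
            continue
        classified.append(rec)
        by_stratum[tr.completeness].append(rec)
    manifest.n_analysed = len(classified)

    both = by_stratum[Completeness.BOTH_MEASURED]
    family_table = sensitivity_table(both) if both else None

    crude = short_stature_sensitivity(classified) if classified else (0, 0, 0.0)

    bw_result = None
    bw_records = [r for r in classified if r.bw_sds is not None]
    kept = [r for r in bw_records if abs(r.bw_sds) <= config.bw_outlier_sds]
    for r in bw_records:
        if abs(r.bw_sds) > config.bw_outlier_sds:
            manifest.bw_exclusions.append(
                (r.id, f"birthweight outlier |{r.bw_sds:.2f}| > "
                       f"{config.bw_outlier_sds:g} SDS")
            )
    if kept:
        bw_result = birthweight_sensitivity(kept, config.bw_cutoffs)

    summaries: dict[Completeness, StratumSummary] = {}
    for c, rs in by_stratum.items():
        if not rs:
            continue
        mean_ht = sum(r.ht_sds for r in rs) / len(rs)
        if all(r.ltr_sds is not None for r in rs):
            mean_ltr = sum(r.ltr_sds for r in rs) / len(rs)
            diff = mean_ltr - mean_ht
        else:
            mean_ltr = diff = None
        summaries[c] = StratumSummary(len(rs), mean_ht, mean_ltr, diff)

    return AnalysisResult(
        classified=classified,
        by_stratum=by_stratum,
        family_table=family_table,
        crude_short=crude,
        birthweight=bw_result,
        stratum_summaries=summaries,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Packaged fixture: girls at or above their lower target range
# ---------------------------------------------------------------------------

class FixtureIntegrityError(Exception):
    """The packaged fixture does not match its recorded checksum."""


@dataclass(frozen=True)
class Table3Girl:
    """One fixture girl with pre-computed SDS values."""

    id: str
    karyotype: Karyotype
    age_years: float
    ht_sds: float
    ltr_sds: float
    bw_sds: float | None
    comment: str

    def to_classified(
        self, bw_cutoffs: tuple[float, ...] = DEFAULT_BW_CUTOFFS
    ) -> ClassifiedRecord:
        return classify_sds(
            self.id, self.age_years, self.ht_sds, self.ltr_sds,
            self.bw_sds, bw_cutoffs,
        )


def load_table3_fixture() -> list[Table3Girl]:
    """Load the packaged 14-girl at-or-above-LTR fixture.

    The file's SHA-256 is pinned; a mismatch raises
    :class:`FixtureIntegrityError` rather than silently analysing
    corrupted values.
    """
    data = resources.files("turnerscreen").joinpath(_TABLE3_RESOURCE).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _TABLE3_SHA256:
        raise FixtureIntegrityError(
            f"fixture checksum {digest} != expected {_TABLE3_SHA256}"
        )
    reader = csv.DictReader(io.StringIO(data.decode("utf-8")))
    girls = []
    for row in reader:
        girls.append(
            Table3Girl(
                id=row["id"],
                karyotype=Karyotype(row["karyotype"]),
                age_years=float(row["age_years"]),
                ht_sds=float(row["ht_sds"]),
                ltr_sds=float(row["ltr_sds"]),
                bw_sds=None if row["bw_sds"] == "N/A" else float(row["bw_sds"]),
                comment=row["comment"],
            )
        )
    return girls


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def write_long_results(result: AnalysisResult, path) -> None:
    """Machine-readable long-format results CSV: section,item,n,count,percent."""
    rows = [["section", "item", "n", "count", "percent"]]
    n_short, n_total, pct = result.crude_short
    rows.append(["crude_short_stature", "ht_sds_lt_minus2", n_total, n_short, pct])
    ft = result.family_table
    if ft is not None:
        for band, counts in ft.bands.items():
            rows.append([
                "family_table", f"below_ltr[{BAND_LABELS[band]}]",
                counts.n_total, counts.n_below_ltr,
                ft.percent_below_ltr(band) if counts.n_total else "",
            ])
            rows.append([
                "family_table", f"short_population[{BAND_LABELS[band]}]",
                counts.n_total, counts.n_short_population,
                ft.percent_short_population(band) if counts.n_total else "",
            ])
        rows.append([
            "family_table", "below_ltr[overall]", ft.overall.n_total,
            ft.overall.n_below_ltr, ft.percent_below_ltr(),
        ])
        rows.append([
            "family_table", "short_population[overall]", ft.overall.n_total,
            ft.overall.n_short_population, ft.percent_short_population(),
        ])
    if result.birthweight:
        for cutoff, (count, pct) in sorted(result.birthweight.items()):
            rows.append(["birthweight", f"bw_sds_lt_{cutoff:g}", "", count, pct])
    for c, s in result.stratum_summaries.items():
        rows.append([
            "stratum", f"mean_ltr_minus_ht[{c.value}]", s.n, "",
            "" if s.mean_ltr_minus_ht is None else round(s.mean_ltr_minus_ht, 4),
        ])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        csv.writer(fh, lineterminator="\n").writerows(rows)


def write_family_table_csv(table: SensitivityTable, path) -> None:
    """Wide contingency-table layout: one column per age band plus overall."""
    bands = list(table.bands)
    header = ["row"] + [BAND_LABELS[b] for b in bands] + ["overall"]

    def line(label, getter, pct):
        cells = [getter(table.bands[b]) for b in bands] + [getter(table.overall)]
        if pct:
            cells = [
                format_percent(c, t.n_total) if t.n_total else ""
                for c, t in zip(
                    cells, [table.bands[b] for b in bands] + [table.overall]
                )
            ]
        return [label] + cells

    rows = [
        header,
        line("n", lambda c: c.n_total, False),
        line("below LTR SDS (n)", lambda c: c.n_below_ltr, False),
        line("below LTR SDS (%)", lambda c: c.n_below_ltr, True),
        line("at/above LTR SDS (n)", lambda c: c.n_at_or_above_ltr, False),
        line("at/above LTR SDS (%)", lambda c: c.n_at_or_above_ltr, True),
        line("Ht SDS < -2 (n)", lambda c: c.n_short_population, False),
        line("Ht SDS < -2 (%)", lambda c: c.n_short_population, True),
        line("Ht SDS >= -2 (n)", lambda c: c.n_not_short, False),
        line("Ht SDS >= -2 (%)", lambda c: c.n_not_short, True),
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        csv.writer(fh, lineterminator="\n").writerows(rows)


def write_manifest(manifest: RunManifest, path) -> None:
    doc = {
        "cohort_path": manifest.cohort_path,
        "config_digest": manifest.config_digest,
        "seed": manifest.seed,
        "n_input": manifest.n_input,
        "n_analysed": manifest.n_analysed,
        "exclusions": [list(e) for e in manifest.exclusions],
        "bw_exclusions": [list(e) for e in manifest.bw_exclusions],
        "timestamp": manifest.timestamp,
        "outputs": manifest.outputs,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
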