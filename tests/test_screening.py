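"""Classification thresholds, age-banded tables, birthweight cut-offs,
and the population-scale worked example."""

import numpy as np
import pytest

from turnerscreen import (
    AgeBand,
    ExcludedRecordError,
    birthweight_sensitivity,
    classify_sds,
    crude_screening_yield,
    format_percent,
    sensitivity_table,
    short_stature_sensitivity,
)


def rec(i, age, ht, ltr=None, bw=None):
    return classify_sds(f"g{i}", age, ht, ltr, bw)


class TestClassification:
    @pytest.mark.parametrize(
        "ht,ltr,below_family,short_pop",
        [
            # published fixture rows: above family range, one also short
            (-1.52, -2.45, False, False),
            (-2.15, -2.78, False, True),
            (-2.50, -2.10, True, True),
        ],
    )
    def test_family_and_population_flags(self, ht, ltr, below_family, short_pop):
        r = rec(0, 3.0, ht, ltr)
        assert r.below_family is below_family
        assert r.short_population is short_pop

    def test_exactly_minus_two_is_not_short(self):
        # strict inequality: a girl at exactly -2.00 is in the not-short group
        assert rec(0, 6.0, -2.0).short_population is False
        assert rec(0, 6.0, -2.0000001).short_population is True

    def test_exactly_at_ltr_is_not_below_family(self):
        assert rec(0, 6.0, -1.8, ltr=-1.8).below_family is False

    def test_no_ltr_leaves_family_flag_undefined(self):
        assert rec(0, 6.0, -2.5).below_family is None

    def test_age_at_or_below_one_year_is_excluded_signal(self):
        with pytest.raises(ExcludedRecordError) as exc:
            rec(0, 0.9, -2.5)
        assert "1 year" in exc.value.reason

    @pytest.mark.parametrize(
        "age,band",
        [
            (1.31, AgeBand.BAND_1_5), (5.0, AgeBand.BAND_1_5),
            (5.01, AgeBand.BAND_5_10), (10.0, AgeBand.BAND_5_10),
            (10.1, AgeBand.BAND_10_16), (16.0, AgeBand.BAND_10_16),
            (16.5, AgeBand.OUT_OF_BAND),
        ],
    )
    def test_age_banding(self, age, band):
        assert rec(0, age, -2.5).age_band == band


def build_banded(counts):
    """counts: {band-age: (n_total, n_below_ltr, n_short)} -> records."""
    records = []
    i = 0
    for age, (n, n_below, n_short) in counts.items():
        for j in range(n):
            ht = -2.5 if j < n_short else -1.5
            ltr = ht + 0.3 if j < n_below else ht - 0.3
            records.append(rec(i := i + 1, age, ht, ltr))
    return records


class TestSensitivityTable:
    def test_published_band_counts_reproduce_published_percentages(self):
        # contingency 28/38, 27/30, 21/24 per band -> overall 76/92 (83%)
        records = build_banded({3.0: (38, 28, 27), 7.0: (30, 27, 25),
                                12.0: (24, 21, 22)})
        t = sensitivity_table(records)
        assert t.overall.n_total == 92
        assert t.overall.n_below_ltr == 76
        assert t.percent_below_ltr() == 83
        assert t.percent_below_ltr(AgeBand.BAND_1_5) == 74
        assert t.percent_below_ltr(AgeBand.BAND_5_10) == 90
        assert t.percent_below_ltr(AgeBand.BAND_10_16) == 88
        # population rows of the same table
        assert t.overall.n_short_population == 74
        assert t.percent_short_population() == 80
        assert t.percent_short_population(AgeBand.BAND_1_5) == 71

    def test_partition_identities(self):
        records = build_banded({2.0: (10, 7, 6), 8.0: (9, 8, 8), 13.0: (5, 5, 4)})
        t = sensitivity_table(records)
        for counts in [*t.bands.values(), t.overall]:
            assert counts.n_below_ltr + counts.n_at_or_above_ltr == counts.n_total
            assert counts.n_short_population + counts.n_not_short == counts.n_total
        assert sum(b.n_total for b in t.bands.values()) == t.overall.n_total

    def test_all_below_gives_full_sensitivity(self):
        records = [rec(i, 4.0, -3.0, -2.0) for i in range(7)]
        t = sensitivity_table(records)
        assert t.percent_below_ltr() == 100
        assert t.sensitivity_below_ltr() == 1.0

    def test_order_independence(self):
        records = build_banded({3.0: (8, 5, 4), 9.0: (6, 5, 5)})
        t1 = sensitivity_table(records)
        t2 = sensitivity_table(list(reversed(records)))
        assert t1 == t2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_table([])

    def test_records_without_ltr_rejected(self):
        with pytest.raises(ValueError, match="LTR"):
            sensitivity_table([rec(0, 4.0, -2.5)])


class TestCrudeShortStature:
    def test_cohort_percentage_to_one_decimal(self):
        records = [rec(i, 6.0, -2.5) for i in range(142)]
        records += [rec(200 + i, 3.0, -1.5) for i in range(30)]
        n_short, n_total, pct = short_stature_sensitivity(records)
        assert (n_short, n_total) == (142, 172)
        assert pct == 82.6


class TestBirthweight:
    def test_published_counts_and_percentages(self):
        # 15 below -2, 36 below -1.5, 65 below -1, denominator 135
        bws = ([-2.5] * 15 + [-1.7] * 21 + [-1.2] * 29 + [-0.5] * 70)
        records = [rec(i, 5.0, -2.5, bw=b) for i, b in enumerate(bws)]
        out = birthweight_sensitivity(records)
        assert out[-2.0] == (15, 11.1)
        assert out[-1.5] == (36, 26.7)
        assert out[-1.0] == (65, 48.1)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(42)
        records = [
            rec(i, 5.0, -2.0, bw=b)
            for i, b in enumerate(rng.normal(-0.9, 1.1, 200))
        ]
        cutoffs = (-3.0, -2.0, -1.5, -1.0, 0.0, 1.0)
        out = birthweight_sensitivity(records, cutoffs)
        counts = [out[c][0] for c in cutoffs]
        assert counts == sorted(counts)

    def test_matches_empirical_cdf_on_uniform_draws(self):
        rng = np.random.default_rng(7)
        bws = rng.uniform(-3, 1, size=400)
        records = [rec(i, 5.0, -2.0, bw=b) for i, b in enumerate(bws)]
        out = birthweight_sensitivity(records, (-2.0, -1.0, 0.0))
        for c in (-2.0, -1.0, 0.0):
            brute = int(np.sum(bws < c))  # independent count oracle
            assert out[c][0] == brute
            assert out[c][1] == format_percent(brute, 400, 1)

    def test_extreme_cutoff_counts_nothing(self):
        records = [rec(i, 5.0, -2.0, bw=-1.0) for i in range(5)]
        assert birthweight_sensitivity(records, (-10.0,))[-10.0][0] == 0

    def test_no_birthweights_rejected(self):
        with pytest.raises(ValueError):
            birthweight_sensitivity([rec(0, 5.0, -2.0)])


class TestCrudeScreeningYield:
    def test_national_worked_example_with_compat_rounding(self):
        y = crude_screening_yield(53802, 0.5, 1 / 2000, 3.0, paper_compat=True)
        assert y.n_short_girls == 800
        assert y.n_ts_girls == 13
        assert y.ppv_percent == 1.6

    def test_exact_mode_direct_arithmetic(self):
        y = crude_screening_yield(53802, 0.5, 1 / 2000, 3.0, paper_compat=False)
        assert y.n_short_girls == pytest.approx(807.03)
        assert round(y.n_short_girls) == 807
        assert y.n_ts_girls == pytest.approx(13.4505)
        assert y.ppv_percent == pytest.approx(100 * (1 / 2000) / 0.03)

    def test_zero_prevalence_gives_zero_ppv(self):
        assert crude_screening_yield(50000, 0.5, 0.0, 3.0).ppv_percent == 0.0

    @pytest.mark.parametrize("centile", [0.0, 100.0, -1.0])
    def test_bad_centile_rejected(self, centile):
        with pytest.raises(ValueError):
            crude_screening_yield(50000, 0.5, 1 / 2000, centile)


class TestPercentFormatting:
    @pytest.mark.parametrize(
        "num,den,decimals,expected",
        [
            (78, 92, 0, 85),      # 84.78 rounds up
            (27, 38, 0, 71),      # 71.05
            (74, 92, 0, 80),      # 80.43
            (21, 24, 0, 88),      # 87.5 -> half-to-even -> 88
            (142, 172, 1, 82.6),
            (36, 135, 1, 26.7),
            (13, 800, 1, 1.6),    # 1.625 -> 1.6
            (94, 172, 1, 54.7),   # 54.65...
        ],
    )
    def test_round_half_even_display(self, num, den, decimals, expected):
        assert format_percent(num, den, decimals) == expected

    def test_truncation_compat_mode(self):
        assert format_percent(94, 172, 1, truncate=True) == 54.6
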