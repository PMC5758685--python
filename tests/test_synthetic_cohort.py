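"""Synthetic Turner-cohort generator: determinism, calibration recovery,
CSV round trip."""

import numpy as np
import pytest
from scipy import stats

from turnerscreen import (
    Completeness,
    GirlRecord,
    HeightSource,
    Karyotype,
    Measurement,
    ParentalHeights,
    SimulationConfig,
    TurnerDeficit,
    default_turner_config,
    expected_statistics,
    lms_zscore,
    read_cohort,
    run_analysis,
    simulate_cohort,
    turner_deficit,
    write_cohort,
)
from turnerscreen.synthetic_cohort import cohort_to_csv_text


class TestTurnerDeficit:
    def test_plateau_before_knot(self):
        p = TurnerDeficit(deficit_at_1y=-2.0, slope_after_plateau=-0.1, plateau_age=4.0)
        for age in (1.0, 2.5, 4.0):
            assert turner_deficit(age, p) == -2.0

    def test_linear_decline_after_knot(self):
        p = TurnerDeficit(deficit_at_1y=-2.0, slope_after_plateau=-0.1, plateau_age=4.0)
        assert turner_deficit(5.0, p) == pytest.approx(-2.1)
        assert turner_deficit(14.0, p) == pytest.approx(-3.0)

    def test_continuous_and_non_increasing(self):
        p = TurnerDeficit()
        ages = np.linspace(1.0, 18.5, 300)
        d = turner_deficit(ages, p)
        assert np.all(np.diff(d) <= 1e-12)
        knee = p.plateau_age
        assert turner_deficit(knee - 1e-9, p) == pytest.approx(
            turner_deficit(knee + 1e-9, p), abs=1e-6
        )


class TestConfigValidation:
    def test_probabilities_must_sum_to_one(self):
        cfg = default_turner_config()
        bad = SimulationConfig.from_dict(
            {**cfg.to_dict(), "parental_measurement_missingness": [0.5, 0.2, 0.2]}
        )
        with pytest.raises(ValueError, match="sums to"):
            bad.validate()

    def test_karyotype_mix_must_sum_to_one(self):
        cfg = default_turner_config()
        d = cfg.to_dict()
        d["karyotype_mix"]["45X"] += 0.1
        with pytest.raises(ValueError, match="karyotype_mix"):
            SimulationConfig.from_dict(d).validate()

    def test_validation_errors_before_sampling(self, height_ref, bw_ref):
        cfg = SimulationConfig(n_girls=0)
        with pytest.raises(ValueError):
            simulate_cohort(cfg, height_ref, bw_ref)

    def test_yaml_round_trip(self):
        cfg = default_turner_config(n_girls=17, seed=3)
        assert SimulationConfig.from_yaml(cfg.to_yaml()) == cfg


class TestDeterminism:
    def test_same_seed_gives_byte_identical_cohort(self, height_ref, bw_ref):
        cfg = default_turner_config(n_girls=60, seed=11)
        a = cohort_to_csv_text(simulate_cohort(cfg, height_ref, bw_ref))
        b = cohort_to_csv_text(simulate_cohort(cfg, height_ref, bw_ref))
        assert a == b

    def test_different_seeds_differ(self, height_ref, bw_ref):
        a = simulate_cohort(default_turner_config(60, seed=1), height_ref, bw_ref)
        b = simulate_cohort(default_turner_config(60, seed=2), height_ref, bw_ref)
        assert cohort_to_csv_text(a) != cohort_to_csv_text(b)


class TestDegenerateNoise:
    def test_zero_noise_zero_coupling_height_equals_deficit(self, height_ref):
        d = default_turner_config(n_girls=40, seed=5).to_dict()
        d.update(
            residual_sd=0.0,
            parent_child_coupling=0.0,
            karyotype_mix={"45X": 1.0},
        )
        cfg = SimulationConfig.from_dict(d)
        for g in simulate_cohort(cfg, height_ref):
            z = lms_zscore(
                Measurement(g.height_cm, g.age_first_measurement), height_ref
            )
            expected = turner_deficit(g.age_first_measurement, cfg.turner_deficit)
            assert z == pytest.approx(expected, abs=1e-9)


N_BIG = 10_000


@pytest.fixture(scope="module")
def big_run(height_ref, bw_ref):
    cfg = default_turner_config(n_girls=N_BIG, seed=2024)
    cohort = simulate_cohort(cfg, height_ref, bw_ref)
    result = run_analysis(cohort, height_ref, bw_ref)
    return cfg, cohort, result


class TestCalibrationRecovery:
    """Monte-Carlo estimates vs the generator's own analytic expectations."""

    N = N_BIG

    def test_mean_ht_and_ltr_sds_recover_expectations(self, height_ref, big_run):
        cfg, _, result = big_run
        exp = expected_statistics(cfg, height_ref)
        ht = np.array([r.ht_sds for r in result.classified])
        assert ht.mean() == pytest.approx(
            exp.mean_ht_sds, abs=3 * exp.sd_ht_sds / np.sqrt(self.N)
        )
        assert ht.std() == pytest.approx(exp.sd_ht_sds, rel=0.05)
        both = result.by_stratum[Completeness.BOTH_MEASURED]
        ltr = np.array([r.ltr_sds for r in both])
        assert ltr.mean() == pytest.approx(
            exp.mean_ltr_sds, abs=3 * exp.sd_ltr_sds / np.sqrt(len(both))
        )

    def test_below_ltr_rate_matches_gaussian_oracle(self, height_ref, big_run):
        cfg, _, result = big_run
        exp = expected_statistics(cfg, height_ref)
        both = result.by_stratum[Completeness.BOTH_MEASURED]
        rate = np.mean([r.below_family for r in both])
        se = np.sqrt(exp.p_below_ltr * (1 - exp.p_below_ltr) / len(both))
        assert rate == pytest.approx(exp.p_below_ltr, abs=3 * se)

    def test_karyotype_mix_passes_goodness_of_fit(self, big_run):
        cfg, cohort, _ = big_run
        observed = {k: 0 for k in cfg.karyotype_mix}
        for g in cohort:
            observed[g.karyotype] += 1
        obs = np.array([observed[k] for k in cfg.karyotype_mix])
        expected = self.N * np.array(list(cfg.karyotype_mix.values()))
        _, p = stats.chisquare(obs, expected)
        assert p > 0.01

    def test_family_sensitivity_rises_with_age_band(self, height_ref, big_run):
        # the deficit deepens after the plateau, so older bands are caught more
        _, _, result = big_run
        t = result.family_table
        rates = [
            b.n_below_ltr / b.n_total for b in t.bands.values() if b.n_total > 0
        ]
        assert rates == sorted(rates)

    def test_birthweight_sds_centre_recovers_config(self, height_ref, bw_ref, big_run):
        cfg, _, result = big_run
        bw = np.array([r.bw_sds for r in result.classified if r.bw_sds is not None])
        mean, sd = cfg.bw_sds_distribution
        assert bw.mean() == pytest.approx(mean, abs=3 * sd / np.sqrt(bw.size))


class TestCohortCSV:
    def girls(self):
        return [
            GirlRecord(
                "a", 4.5, height_cm=95.2, karyotype=Karyotype.MONOSOMY_45X,
                birthweight_g=2810.0, gestation_weeks=39.0,
                parents=ParentalHeights(161.3, 177.9),
            ),
            GirlRecord(
                "b", 9.1, height_sds=-2.02, karyotype=Karyotype.XX_MOSAIC,
                parents=ParentalHeights(
                    158.0, None, HeightSource.MEASURED, HeightSource.MISSING
                ),
            ),
        ]

    def test_round_trip_equality(self, tmp_path):
        path = tmp_path / "cohort.csv"
        girls = self.girls()
        write_cohort(girls, path)
        assert read_cohort(path) == girls

    def test_missing_father_survives_round_trip(self, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(self.girls(), path)
        back = read_cohort(path)
        assert back[1].parents.father_cm is None
        assert back[1].parents.father_source == HeightSource.MISSING

    def test_empty_cohort_is_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_cohort([], path)
        assert path.read_text().count("\n") == 1
        assert read_cohort(path) == []

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,age\nx,3\n")
        with pytest.raises(ValueError, match="header"):
            read_cohort(path)

    def test_row_errors_carry_line_numbers(self, tmp_path):
        path = tmp_path / "bad.csv"
        girls = self.girls()
        write_cohort(girls, path)
        text = path.read_text().replace("45X", "46XX-nonsense")
        path.write_text(text)
        with pytest.raises(ValueError, match="line 2"):
            read_cohort(path)

    def test_simulated_cohort_round_trips(self, tmp_path, height_ref, bw_ref):
        cohort = simulate_cohort(default_turner_config(30, seed=9), height_ref, bw_ref)
        path = tmp_path / "sim.csv"
        write_cohort(cohort, path)
        assert read_cohort(path) == cohort
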