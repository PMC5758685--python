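"""Simulate a calibrated synthetic Turner cohort and run the full analysis.

The generator draws ages, parental heights, karyotypes and latent height
SDS from a Gaussian model calibrated to a clinic cohort's statistics
(mean Ht SDS -2.63, SD 0.94; mean LTR SDS -1.77).  The pipeline then
re-derives every SDS from raw centimetres, builds the target ranges, and
reports population- and family-referenced screening sensitivity by age
band.
"""

from turnerscreen import (
    Completeness,
    default_turner_config,
    expected_statistics,
    run_analysis,
    simulate_cohort,
    synthetic_birthweight_reference,
    synthetic_female_height_reference,
)
from turnerscreen.screening import BAND_LABELS

height_ref = synthetic_female_height_reference()
bw_ref = synthetic_birthweight_reference()

cfg = default_turner_config(n_girls=2000, seed=42)
cohort = simulate_cohort(cfg, height_ref, bw_ref)
result = run_analysis(cohort, height_ref, bw_ref)

exp = expected_statistics(cfg, height_ref)
print(f"analytic model expectations: mean Ht SDS {exp.mean_ht_sds:.2f}, "
      f"mean LTR SDS {exp.mean_ltr_sds:.2f}, P(below LTR) {exp.p_below_ltr:.3f}")

n_short, n_total, pct = result.crude_short
print(f"\ncrude short stature (Ht SDS < -2): {n_short}/{n_total} ({pct}%)")

t = result.family_table
print(f"below family LTR (both parents measured): "
      f"{t.overall.n_below_ltr}/{t.overall.n_total} ({t.percent_below_ltr()}%)")
for band, counts in t.bands.items():
    if counts.n_total:
        print(f"  {BAND_LABELS[band]:14} {counts.n_below_ltr:4}/{counts.n_total:<4} "
              f"({t.percent_below_ltr(band)}%)")

print("\nmean(LTR - Ht) SDS by parental stratum:")
for c in (Completeness.BOTH_MEASURED, Completeness.ONE_MEASURED,
          Completeness.BOTH_REPORTED):
    s = result.stratum_summaries.get(c)
    if s:
        print(f"  {c.value:14} {s.mean_ltr_minus_ht:+.2f}  (n={s.n})")
print("\n(the family criterion catches more girls in older bands because the")
print(" Turner height deficit deepens after the age-4 plateau)")
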