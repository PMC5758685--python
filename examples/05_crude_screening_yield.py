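"""Why crude short-stature screening alone cannot find Turner syndrome.

A back-of-envelope national calculation: of ~53,800 annual live births,
half are girls; 3% of girls are by definition below the 3rd height
centile, but Turner syndrome affects only ~1 in 2000 girls.  The
positive predictive value of "short girl -> karyotype" is therefore tiny.
"""

from turnerscreen import crude_screening_yield

y = crude_screening_yield(
    annual_births=53802, female_fraction=0.5, ts_prevalence=1 / 2000,
    short_centile=3.0, paper_compat=True,
)
print(f"girls below the 3rd centile each year : ~{y.n_short_girls:.0f}")
print(f"of whom with Turner syndrome          : ~{y.n_ts_girls:.0f}")
print(f"positive predictive value             : {y.ppv_percent}%")

exact = crude_screening_yield(53802, 0.5, 1 / 2000, 3.0, paper_compat=False)
print(f"\nexact arithmetic: {exact.n_short_girls:.2f} short girls, "
      f"{exact.n_ts_girls:.4f} affected, PPV {exact.ppv_percent:.2f}%")
print("\nkaryotyping every short girl would test ~60 girls per case found —")
print("hence the case for judging height against the family's target range.")
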