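"""The packaged 14-girl fixture: the false negatives of family screening.

These are published values for girls whose first accurate height
measurement fell at or above the lower end of their parental target
range — the girls that even family-referenced screening misses.  Most
are under 5 (Turner growth failure accelerates after age ~4) or carry a
milder mosaic karyotype.
"""

from turnerscreen import Karyotype, load_table3_fixture

girls = load_table3_fixture()
print(f"{'id':6} {'karyotype':12} {'age':>5} {'Ht SDS':>7} {'LTR SDS':>8}")
for g in girls:
    print(f"{g.id:6} {g.karyotype.value:12} {g.age_years:5.2f} "
          f"{g.ht_sds:7.2f} {g.ltr_sds:8.2f}")

n_young = sum(g.age_years < 5 for g in girls)
n_mild = sum(g.karyotype in (Karyotype.XX_MOSAIC, Karyotype.TRIPLE_X_MOSAIC)
             for g in girls)
print(f"\n{len(girls)} girls at/above their LTR; {n_young} aged < 5 years; "
      f"{n_mild} with milder mosaic karyotypes")
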