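"""Mid-parental height and the lower end of the parental target range.

For a daughter, MPH = (mother + father - 12.5)/2 and LTR = MPH - 8.5 cm
(about two SDs of adult height below MPH).  Both are expressed as SDS at
age 20 so a girl's height SDS can be compared with her family's range:
a girl below her LTR is short *for her family* even if she is not short
for the population.
"""

from turnerscreen import (
    ParentalHeights,
    lower_target_range,
    mid_parental_height,
    synthetic_female_height_reference,
    target_range_sds,
)

ref = synthetic_female_height_reference()
parents = ParentalHeights(mother_cm=163.1, father_cm=176.4)

mph = mid_parental_height(parents)
ltr = lower_target_range(mph)
tr = target_range_sds(parents, ref)

print(f"mother 163.1 cm, father 176.4 cm")
print(f"MPH = {mph:.1f} cm  (SDS {tr.mph_sds:+.2f} at age 20)")
print(f"LTR = {ltr:.1f} cm  (SDS {tr.ltr_sds:+.2f})")
print(f"stratum: {tr.completeness.value}")
print()
print("a girl of this family with Ht SDS -1.6 is not short for the")
print(f"population (>= -2) but IS below her family range "
      f"({-1.6:.1f} < {tr.ltr_sds:.2f})" if -1.6 < tr.ltr_sds else
      f"population (>= -2) and also at/above her family range "
      f"(-1.60 >= {tr.ltr_sds:.2f})")
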